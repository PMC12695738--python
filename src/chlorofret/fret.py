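"""Förster energy-transfer rate networks between chlorophylls.

In the point-dipole approximation the donor→acceptor transfer rate is

    K_DA = C · κ² / (n⁴ · R⁶)

where ``C`` is a constant absorbing the spectral overlap between the two
pigments, ``n`` the refractive index of the protein medium, ``R`` the
center-to-center (Mg–Mg) distance, and κ² the orientation factor

    κ² = [ û_D·û_A − 3 (û_D·R̂)(û_A·R̂) ]²  ∈ [0, 4],

with û_D, û_A the transition-dipole unit vectors (taken along the N_B→N_D
axis of the chlorin ring) and R̂ the unit Mg→Mg separation vector.

Unit convention: with the default ``C = 32.26`` the distance enters in nm and
the rate comes out in ns⁻¹; ``R`` arguments and the cutoff stay in Å like all
other coordinates, the conversion happens inside :func:`fret_rate`.  Only
Chl a → Chl a pairs are connected by default because the overlap constant for
chlorophyll c is not established; supply per-pair C values through
``FretParameters.pair_c`` to extend the rule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import SiteId

MIN_DIPOLE_LENGTH = 0.1  # Å; NB/ND closer than this leaves the dipole undefined


class PairExcludedError(ValueError):
    """The pair rule excludes this donor/acceptor combination."""


@dataclass(frozen=True)
class Chlorophyll:
    """A chlorophyll site reduced to its Mg center and Qy dipole axis."""

    site_id: SiteId
    kind: str  # "chl_a" or "chl_c"
    mg: np.ndarray
    nb: np.ndarray
    nd: np.ndarray

    def __post_init__(self):
        for name in ("mg", "nb", "nd"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        if self.kind not in ("chl_a", "chl_c"):
            raise ValueError(f"kind must be chl_a or chl_c, got {self.kind!r}")

    @property
    def dipole(self) -> np.ndarray:
        """Unit vector along N_B → N_D; undefined below MIN_DIPOLE_LENGTH."""
        d = self.nd - self.nb
        norm = np.linalg.norm(d)
        if norm < MIN_DIPOLE_LENGTH:
            raise ValueError(
                f"chlorophyll {self.site_id}: |ND - NB| = {norm:.3g} Å, dipole undefined"
            )
        return d / norm


@dataclass
class FretParameters:
    """Constants of the rate formula and the network-building rules.

    c_factor : overlap constant for Chl a → Chl a (dimensionless in the
        nm/ns convention; default 32.26).
    refractive_index : n of the protein medium (default 1.55).
    cutoff : inclusive Mg–Mg edge cutoff in Å (default 20).
    pair_rule : "chl_a_only" (default) or "custom" with per-pair constants
        in ``pair_c`` keyed by frozenset of kinds, e.g.
        ``{frozenset({"chl_a", "chl_c"}): 10.0}``.
    """

    c_factor: float = 32.26
    refractive_index: float = 1.55
    cutoff: float = 20.0
    pair_rule: str = "chl_a_only"
    pair_c: Mapping[frozenset, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.c_factor <= 0:
            raise ValueError("c_factor must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.pair_rule not in ("chl_a_only", "custom"):
            raise ValueError(f"unknown pair_rule {self.pair_rule!r}")

    def pair_constant(self, kind_a: str, kind_b: str) -> float | None:
        """C for this pair, or None if the rule excludes it."""
        if self.pair_rule == "chl_a_only":
            return self.c_factor if kind_a == kind_b == "chl_a" else None
        key = frozenset((kind_a, kind_b))
        if kind_a == kind_b == "chl_a":
            return self.pair_c.get(key, self.c_factor)
        return self.pair_c.get(key)


def mg_distance(a: Chlorophyll, b: Chlorophyll) -> float:
    """Center-to-center (Mg–Mg) distance in Å."""
    d = float(np.linalg.norm(a.mg - b.mg))
    if d == 0.0:
        raise ValueError(f"chlorophylls {a.site_id} and {b.site_id} have coincident Mg")
    return d


def kappa_squared(donor: Chlorophyll, acceptor: Chlorophyll) -> float:
    """Orientation factor κ² in [0, 4]; R̂ is taken along the Mg→Mg axis."""
    r = acceptor.mg - donor.mg
    norm = np.linalg.norm(r)
    if norm == 0.0:
        raise ValueError("coincident Mg positions: κ² undefined")
    r_hat = r / norm
    ud, ua = donor.dipole, acceptor.dipole
    kappa = ud @ ua - 3.0 * (ud @ r_hat) * (ua @ r_hat)
    return float(kappa * kappa)


def fret_rate(
    donor: Chlorophyll, acceptor: Chlorophyll, params: FretParameters | None = None
) -> float:
    """Transfer rate K_DA in ns⁻¹ (distance converted to nm internally).

    Raises :class:`PairExcludedError` when the pair rule has no overlap
    constant for this kind combination — never a silent zero.
    """
    params = params if params is not None else FretParameters()
    c = params.pair_constant(donor.kind, acceptor.kind)
    if c is None:
        raise PairExcludedError(
            f"pair {donor.kind}/{acceptor.kind} excluded under rule "
            f"{params.pair_rule!r} (no overlap constant)"
        )
    r_nm = mg_distance(donor, acceptor) / 10.0
    return c * kappa_squared(donor, acceptor) / (params.refractive_index**4 * r_nm**6)


@dataclass(frozen=True)
class FretEdge:
    """Undirected chl a pair: K_DA is symmetric because C is the same both ways."""

    donor: SiteId
    acceptor: SiteId
    separation: float  # Å
    kappa_sq: float
    rate: float  # ns⁻¹

    @property
    def key(self) -> tuple[SiteId, SiteId]:
        return tuple(sorted((self.donor, self.acceptor)))  # type: ignore[return-value]


@dataclass
class FretNetwork:
    model_id: str
    nodes: list[SiteId]          # all extracted chlorophylls (chl c unconnected)
    edges: list[FretEdge]
    node_kind: dict[SiteId, str] = field(default_factory=dict)

    def edge_map(self) -> dict[tuple[SiteId, SiteId], FretEdge]:
        return {e.key: e for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model_id": self.model_id,
                "donor_chain": e.donor[0],
                "donor_seq": e.donor[1],
                "acceptor_chain": e.acceptor[0],
                "acceptor_seq": e.acceptor[1],
                "separation_A": e.separation,
                "kappa_sq": e.kappa_sq,
                "rate_ns": e.rate,
            }
            for e in sorted(self.edges, key=lambda e: e.key)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "model_id", "donor_chain", "donor_seq", "acceptor_chain",
                "acceptor_seq", "separation_A", "kappa_sq", "rate_ns",
            ],
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(model_id=self.model_id)
        for n in self.nodes:
            g.add_node("/".join(map(str, n)), kind=self.node_kind.get(n, "chl_a"))
        for e in self.edges:
            g.add_edge(
                "/".join(map(str, e.donor)),
                "/".join(map(str, e.acceptor)),
                separation=e.separation,
                kappa_sq=e.kappa_sq,
                rate=e.rate,
            )
        return g

    def to_graphml(self, path: str | Path) -> Path:
        path = Path(path)
        nx.write_graphml(self.to_networkx(), str(path))
        return path

    def to_adjacency_tsv(self, path: str | Path) -> Path:
        """Rate-weighted adjacency matrix over connected nodes, for plotting."""
        path = Path(path)
        labels = ["/".join(map(str, n)) for n in self.nodes]
        m = pd.DataFrame(0.0, index=labels, columns=labels)
        for e in self.edges:
            i = "/".join(map(str, e.donor))
            j = "/".join(map(str, e.acceptor))
            m.loc[i, j] = m.loc[j, i] = e.rate
        m.to_csv(path, sep="\t")
        return path


def build_network(
    chlorophylls: list[Chlorophyll],
    params: FretParameters | None = None,
    model_id: str = "",
) -> FretNetwork:
    """Connect every admissible pair within the (inclusive) distance cutoff.

    Uses a k-d tree over Mg centers; equivalent to the brute-force double
    loop over all pairs.
    """
    params = params if params is not None else FretParameters()
    nodes = [c.site_id for c in chlorophylls]
    kinds = {c.site_id: c.kind for c in chlorophylls}
    edges: list[FretEdge] = []
    if len(chlorophylls) >= 2:
        centers = np.array([c.mg for c in chlorophylls])
        tree = cKDTree(centers)
        # small epsilon keeps pairs at exactly the cutoff despite fp rounding
        for i, j in sorted(tree.query_pairs(params.cutoff * (1 + 1e-12))):
            a, b = chlorophylls[i], chlorophylls[j]
            sep = mg_distance(a, b)
            if sep > params.cutoff:
                continue
            if params.pair_constant(a.kind, b.kind) is None:
                continue
            d, ac = sorted((a, b), key=lambda c: c.site_id)
            edges.append(
                FretEdge(
                    donor=d.site_id,
                    acceptor=ac.site_id,
                    separation=sep,
                    kappa_sq=kappa_squared(d, ac),
                    rate=fret_rate(d, ac, params),
                )
            )
    edges.sort(key=lambda e: e.key)
    return FretNetwork(model_id=model_id, nodes=nodes, edges=edges, node_kind=kinds)


def brute_force_network(
    chlorophylls: list[Chlorophyll],
    params: FretParameters | None = None,
    model_id: str = "",
) -> FretNetwork:
    """Reference double-loop enumeration; oracle for :func:`build_network`."""
    params = params if params is not None else FretParameters()
    edges = []
    for a, b in itertools.combinations(chlorophylls, 2):
        if params.pair_constant(a.kind, b.kind) is None:
            continue
        sep = mg_distance(a, b)
        if sep > params.cutoff:
            continue
        d, ac = sorted((a, b), key=lambda c: c.site_id)
        edges.append(
            FretEdge(d.site_id, ac.site_id, sep, kappa_squared(d, ac), fret_rate(d, ac, params))
        )
    edges.sort(key=lambda e: e.key)
    return FretNetwork(
        model_id=model_id,
        nodes=[c.site_id for c in chlorophylls],
        edges=edges,
        node_kind={c.site_id: c.kind for c in chlorophylls},
    )


# ---------------------------------------------------------------------------
# network comparison

@dataclass
class MatchedEdge:
    edge_a: FretEdge
    edge_b: FretEdge
    rate_ratio: float
    status: str  # increased / decreased / equal


@dataclass
class EdgeComparison:
    """Pairing of two networks' edges under a site correspondence."""

    matched: list[MatchedEdge]
    only_in_a: list[FretEdge]
    only_in_b: list[FretEdge]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.matched:
            rows.append(
                {
                    "pathway": _pathway(m.edge_a),
                    "status": m.status,
                    "rate_A": m.edge_a.rate,
                    "rate_B": m.edge_b.rate,
                    "rate_ratio": m.rate_ratio,
                }
            )
        for e in self.only_in_a:
            rows.append({"pathway": _pathway(e), "status": "absent_in_B",
                         "rate_A": e.rate, "rate_B": math.nan, "rate_ratio": math.nan})
        for e in self.only_in_b:
            rows.append({"pathway": _pathway(e), "status": "new_in_B",
                         "rate_A": math.nan, "rate_B": e.rate, "rate_ratio": math.nan})
        return pd.DataFrame(
            rows, columns=["pathway", "status", "rate_A", "rate_B", "rate_ratio"]
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def _pathway(e: FretEdge) -> str:
    return "%s%d/%s-%s%d/%s" % (
        e.donor[2][:1].lower() or "a", e.donor[1], e.donor[0],
        e.acceptor[2][:1].lower() or "a", e.acceptor[1], e.acceptor[0],
    )


def compare_networks(
    net_a: FretNetwork,
    net_b: FretNetwork,
    correspondence: Mapping[SiteId, SiteId],
    rel_tol: float = 0.05,
) -> EdgeComparison:
    """Match edges of A to edges of B through an injective site mapping.

    An edge of A whose endpoints both map and whose image edge exists in B is
    matched; ``rate_ratio = rate_B / rate_A`` and the pair is classified
    ``equal`` when ``|ratio − 1| ≤ rel_tol`` (default 5%, below the rate
    jitter induced by coordinate precision at typical model resolutions),
    otherwise ``increased``/``decreased``.  Remaining edges land in
    ``only_in_a`` / ``only_in_b``.
    """
    values = list(correspondence.values())
    if len(set(values)) != len(values):
        raise ValueError("correspondence must be injective")
    b_edges = net_b.edge_map()
    matched: list[MatchedEdge] = []
    only_a: list[FretEdge] = []
    used_b: set[tuple[SiteId, SiteId]] = set()
    for e in net_a.edges:
        da, aa = correspondence.get(e.donor), correspondence.get(e.acceptor)
        key = tuple(sorted((da, aa))) if da is not None and aa is not None else None
        if key is not None and key in b_edges:
            eb = b_edges[key]
            ratio = eb.rate / e.rate if e.rate > 0 else math.inf
            if abs(ratio - 1.0) <= rel_tol:
                status = "equal"
            elif ratio > 1.0:
                status = "increased"
            else:
                status = "decreased"
            matched.append(MatchedEdge(e, eb, ratio, status))
            used_b.add(key)
        else:
            only_a.append(e)
    only_b = [e for k, e in sorted(b_edges.items()) if k not in used_b]
    return EdgeComparison(matched=matched, only_in_a=only_a, only_in_b=only_b)
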