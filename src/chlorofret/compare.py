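"""Rigid superposition of homologous models and what moves between them.

The workflow mirrors how antenna rearrangements are quantified in
photosystem structure papers: fit a rigid transform on the conserved core
(Cα atoms of PsaA/PsaB for PSI, D1/D2/CP43/CP47 for PSII), apply it to the
whole comparison model, then measure how far each antenna subunit's Cα
centroid moved and which cofactor binding sites match, changed type, or are
present in only one model.  Chain correspondence across species is explicit
user configuration (a chain map, optionally with residue-numbering offsets);
no sequence alignment is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .model import Residue, SiteId, StructureModel

ChainMap = Mapping[str, "str | tuple[str, int]"]


def _normalize_chain_map(chain_map: ChainMap) -> dict[str, tuple[str, int]]:
    out: dict[str, tuple[str, int]] = {}
    for ka, v in chain_map.items():
        if isinstance(v, str):
            out[ka] = (v, 0)
        else:
            chain_b, offset = v
            out[ka] = (str(chain_b), int(offset))
    return out


def load_chain_map(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a YAML chain map: ``A: B`` or ``A: {chain: B, offset: 5}``."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, tuple[str, int]] = {}
    for ka, v in raw.items():
        if isinstance(v, dict):
            out[str(ka)] = (str(v["chain"]), int(v.get("offset", 0)))
        else:
            out[str(ka)] = (str(v), 0)
    return out


@dataclass
class AtomSelection:
    """Predicate over (chain, seq, atom name, category); None = no constraint."""

    chains: Sequence[str] | None = None
    seq_range: tuple[int, int] | None = None
    atom_names: Sequence[str] | None = ("CA",)
    categories: Sequence[str] | None = None

    def admits_residue(self, res: Residue) -> bool:
        if self.chains is not None and res.chain_id not in self.chains:
            return False
        if self.seq_range is not None and not (
            self.seq_range[0] <= res.seq_id <= self.seq_range[1]
        ):
            return False
        if self.categories is not None and res.category not in self.categories:
            return False
        return True

    def admits_atom(self, name: str) -> bool:
        return self.atom_names is None or name in self.atom_names


@dataclass
class Pairing:
    """Matched atom coordinate sets between two models."""

    ids_a: list[tuple[str, int, str]]  # (chain, seq, atom name) in A
    ids_b: list[tuple[str, int, str]]
    coords_a: np.ndarray  # (n, 3)
    coords_b: np.ndarray
    unpaired_a: list[tuple[str, int, str]] = field(default_factory=list)
    unpaired_b: list[tuple[str, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ids_a)


def pair_atoms(
    model_a: StructureModel,
    model_b: StructureModel,
    selection: AtomSelection | None = None,
    chain_map: ChainMap | None = None,
) -> Pairing:
    """Pair atoms (default: Cα) with equal residue number under the chain map.

    ``chain_map`` maps A chains to B chains, optionally with a residue-number
    offset applied on the B side (``seq_b = seq_a + offset``).  Defaults to the
    identity map over A's chains.  Fewer than 3 pairs is an error.
    """
    selection = selection if selection is not None else AtomSelection()
    cmap = _normalize_chain_map(
        chain_map if chain_map is not None else {c: c for c in model_a.chains()}
    )

    index_b: dict[tuple[str, int, str], np.ndarray] = {}
    for res in model_b.residues:
        for atom in res.atoms:
            if selection.admits_atom(atom.name):
                index_b[(res.chain_id, res.seq_id, atom.name)] = atom.position

    ids_a, ids_b, ca, cb = [], [], [], []
    unpaired_a = []
    used_b: set[tuple[str, int, str]] = set()
    for res in model_a.residues:
        if res.chain_id not in cmap or not selection.admits_residue(res):
            continue
        chain_b, offset = cmap[res.chain_id]
        for atom in res.atoms:
            if not selection.admits_atom(atom.name):
                continue
            key_b = (chain_b, res.seq_id + offset, atom.name)
            if key_b in index_b:
                ids_a.append((res.chain_id, res.seq_id, atom.name))
                ids_b.append(key_b)
                ca.append(atom.position)
                cb.append(index_b[key_b])
                used_b.add(key_b)
            else:
                unpaired_a.append((res.chain_id, res.seq_id, atom.name))

    mapped_chains_b = {cb_off[0] for cb_off in cmap.values()}
    unpaired_b = [
        k for k in index_b if k[0] in mapped_chains_b and k not in used_b
    ]
    if len(ids_a) < 3:
        raise ValueError(
            f"only {len(ids_a)} atom pair(s) matched between "
            f"{model_a.model_id} and {model_b.model_id}; need >= 3"
        )
    return Pairing(
        ids_a=ids_a,
        ids_b=ids_b,
        coords_a=np.asarray(ca),
        coords_b=np.asarray(cb),
        unpaired_a=unpaired_a,
        unpaired_b=sorted(unpaired_b),
    )


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping model B onto model A: x ↦ R x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å over the fitted pairs
    n_pairs: int
    pairing: Pairing | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def transform_model(self, model: StructureModel, model_id: str | None = None) -> StructureModel:
        return model.transformed(self.rotation, self.translation, model_id=model_id)

    @classmethod
    def identity(cls) -> "SuperpositionResult":
        return cls(rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0, n_pairs=0)


def superpose(pairing: Pairing) -> SuperpositionResult:
    """Kabsch-type closed-form fit (via quaternion SVD) of B onto A.

    Degenerate (collinear or coincident) atom sets are rejected: the optimal
    rotation is not unique there.
    """
    a, b = pairing.coords_a, pairing.coords_b
    if len(a) < 3:
        raise ValueError("superposition needs at least 3 atom pairs")
    cen_a, cen_b = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - cen_a, b - cen_b
    # rank of the centered cloud: collinear points have ≤ 1 significant axis
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) atom selection: rotation not unique")
    rot, rssd = Rotation.align_vectors(a0, b0)
    rmsd = float(rssd) / np.sqrt(len(a))
    return SuperpositionResult(
        rotation=rot.as_matrix(),
        translation=cen_a - rot.as_matrix() @ cen_b,
        rmsd=rmsd,
        n_pairs=len(a),
        pairing=pairing,
    )


def superpose_models(
    model_a: StructureModel,
    model_b: StructureModel,
    selection: AtomSelection | None = None,
    chain_map: ChainMap | None = None,
) -> SuperpositionResult:
    """Convenience wrapper: pair Cα atoms then fit."""
    return superpose(pair_atoms(model_a, model_b, selection, chain_map))


# ---------------------------------------------------------------------------
# subunit shifts

@dataclass
class SubunitShift:
    """Displacement of one subunit after a core-anchored superposition."""

    subunit_a: str
    subunit_b: str
    centroid_shift: float  # Å
    per_atom_rmsd: float  # Å over paired subunit Cα
    n_atoms: int
    core_rmsd: float

    def to_row(self) -> dict:
        return {
            "subunit": self.subunit_a,
            "centroid_shift_A": self.centroid_shift,
            "per_atom_rmsd_A": self.per_atom_rmsd,
            "n_atoms": self.n_atoms,
            "core_rmsd_A": self.core_rmsd,
        }


def subunit_shift(
    model_a: StructureModel,
    model_b: StructureModel,
    core_chain_map: ChainMap,
    subunit_a: str,
    subunit_b: str | tuple[str, int] | None = None,
    atom_names: Sequence[str] = ("CA",),
) -> SubunitShift:
    """Core-anchored displacement of one subunit between two models.

    The rigid transform is fitted on ``core_chain_map`` only (the subunit
    under test must not be part of the core), applied to B, and the shift is
    the distance between the Cα centroids of the subunit in A and in the
    transformed B, over the paired atoms.
    """
    core = _normalize_chain_map(core_chain_map)
    if subunit_a in core:
        raise ValueError(f"subunit {subunit_a!r} must be excluded from the core anchor")
    if subunit_b is None:
        subunit_b = subunit_a
    sup = superpose_models(
        model_a, model_b, AtomSelection(atom_names=tuple(atom_names)), core
    )
    sub_pairing = pair_atoms(
        model_a,
        model_b,
        AtomSelection(atom_names=tuple(atom_names)),
        {subunit_a: subunit_b},
    )
    if len(sub_pairing) == 0:
        raise ValueError(f"subunit {subunit_a!r} has no paired atoms")
    b_moved = sup.apply(sub_pairing.coords_b)
    centroid_shift = float(
        np.linalg.norm(sub_pairing.coords_a.mean(axis=0) - b_moved.mean(axis=0))
    )
    per_atom_rmsd = float(
        np.sqrt(np.mean(np.sum((sub_pairing.coords_a - b_moved) ** 2, axis=1)))
    )
    sub_b_chain = subunit_b if isinstance(subunit_b, str) else subunit_b[0]
    return SubunitShift(
        subunit_a=subunit_a,
        subunit_b=sub_b_chain,
        centroid_shift=centroid_shift,
        per_atom_rmsd=per_atom_rmsd,
        n_atoms=len(sub_pairing),
        core_rmsd=sup.rmsd,
    )


def shift_report(shifts: Sequence[SubunitShift]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in shifts])


# ---------------------------------------------------------------------------
# cofactor site matching

DEFAULT_SITE_CATEGORIES = ("chl_a", "chl_c", "carotenoid", "lipid")


def _site_center(res: Residue) -> np.ndarray:
    """Chlorophylls are represented by Mg; everything else by its centroid."""
    if res.category in ("chl_a", "chl_c"):
        mg = res.atom("MG")
        if mg is not None:
            return mg.position
    return res.center()


@dataclass
class SiteMatch:
    site_a: SiteId
    site_b: SiteId
    distance: float
    category_a: str
    category_b: str

    @property
    def same_category(self) -> bool:
        return self.category_a == self.category_b


@dataclass
class SiteMatchTable:
    matched: list[SiteMatch]
    only_in_a: list[tuple[SiteId, str]]  # (site, category)
    only_in_b: list[tuple[SiteId, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.matched:
            rows.append(
                {
                    "site_A": "/".join(map(str, m.site_a)),
                    "site_B": "/".join(map(str, m.site_b)),
                    "distance_A": m.distance,
                    "category_A": m.category_a,
                    "category_B": m.category_b,
                    "status": "matched" if m.same_category else "type_change",
                }
            )
        for s, cat in self.only_in_a:
            rows.append({"site_A": "/".join(map(str, s)), "site_B": "", "distance_A": np.nan,
                         "category_A": cat, "category_B": "", "status": "only_A"})
        for s, cat in self.only_in_b:
            rows.append({"site_A": "", "site_B": "/".join(map(str, s)), "distance_A": np.nan,
                         "category_A": "", "category_B": cat, "status": "only_B"})
        return pd.DataFrame(
            rows,
            columns=["site_A", "site_B", "distance_A", "category_A", "category_B", "status"],
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def n_differing(self) -> int:
        """Sites assigned differently: type changes plus one-sided sites."""
        return (
            sum(1 for m in self.matched if not m.same_category)
            + len(self.only_in_a)
            + len(self.only_in_b)
        )


def match_cofactor_sites(
    model_a: StructureModel,
    model_b: StructureModel,
    superposition: SuperpositionResult,
    match_radius: float = 3.0,
    categories: Sequence[str] = DEFAULT_SITE_CATEGORIES,
) -> SiteMatchTable:
    """Greedy nearest-first one-to-one matching of cofactor sites.

    B's representative centers are mapped into A's frame first.  Candidate
    pairs within ``match_radius`` are taken closest-first with a deterministic
    tie-break (site ids); each site is used at most once.  The
    ``same_category`` flag marks type changes such as a chl a site assigned
    as chl c in the other model.
    """
    res_a = [r for r in model_a.residues if r.category in categories]
    res_b = [r for r in model_b.residues if r.category in categories]
    centers_a = [(_site_center(r), r) for r in res_a]
    centers_b = [(superposition.apply(_site_center(r)[None, :])[0], r) for r in res_b]

    candidates = []
    for pa, ra in centers_a:
        for pb, rb in centers_b:
            d = float(np.linalg.norm(pa - pb))
            if d <= match_radius:
                candidates.append((d, ra.site_id, rb.site_id, ra, rb))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_a: set[SiteId] = set()
    used_b: set[SiteId] = set()
    matched: list[SiteMatch] = []
    for d, sa, sb, ra, rb in candidates:
        if sa in used_a or sb in used_b:
            continue
        matched.append(SiteMatch(sa, sb, d, ra.category, rb.category))
        used_a.add(sa)
        used_b.add(sb)
    only_a = [(r.site_id, r.category) for r in res_a if r.site_id not in used_a]
    only_b = [(r.site_id, r.category) for r in res_b if r.site_id not in used_b]
    return SiteMatchTable(matched=matched, only_in_a=only_a, only_in_b=only_b)
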