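"""Synthetic coordinate models with planted ground truth.

Every pipeline stage is exercised on generated structures whose answers are
known by construction: chlorophyll coordination frames (Mg plus four pyrrole
nitrogens) at controlled centers and dipole orientations, ideal-cubane Fe₄S₄
clusters with waters planted at controlled radii, Cα-only protein chains, and
rigid-transformed copies with optional per-chain offsets and coordinate noise.

The minimal chlorophyll representation (Mg + 4 N at 2.05 Å) is deliberate:
the downstream geometry uses only Mg, N_B and N_D, so this is the smallest
sufficient fixture.  Generation is deterministic: equal specs and seeds give
byte-identical files.

The ``psi_supercomplex`` / ``psii_supercomplex`` builders and their variants
are *synthetic stand-ins* for deposited cryo-EM models of cryptophyte
photosystem–antenna supercomplexes: their cofactor composition and the
planted geometric facts (antenna-subunit offsets, specific pigment–pigment
distances, water-shell occupancy and conservation overlap) follow published
descriptions of those structures, while the coordinates themselves are
invented.  They let the full pipeline run end-to-end without any downloads;
they are not the deposited models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .components import classify_cofactors
from .model import Atom, Residue, StructureModel

MG_N_DISTANCE = 2.05  # Å, Mg to pyrrole N in the idealized chlorin frame


def _unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} must be nonzero")
    return v / n


@dataclass
class ChlPlacement:
    """Where a chlorophyll goes and how its ring is oriented."""

    center: np.ndarray
    dipole_direction: np.ndarray  # N_B → N_D axis
    plane_normal: np.ndarray      # ring normal, orthogonal to the dipole
    kind: str = "chl_a"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.dipole_direction = _unit(self.dipole_direction, "dipole_direction")
        self.plane_normal = _unit(self.plane_normal, "plane_normal")
        if abs(self.dipole_direction @ self.plane_normal) > 1e-9:
            raise ValueError("plane_normal must be orthogonal to dipole_direction")
        if self.kind not in ("chl_a", "chl_c"):
            raise ValueError(f"kind must be chl_a or chl_c, got {self.kind!r}")


def make_chlorophyll_frame(
    placement: ChlPlacement, chain_id: str, seq_id: int
) -> Residue:
    """Idealized coordination frame: MG at the center, NA–ND at 2.05 Å.

    The NB→ND axis lies along ``dipole_direction``; NA/NC along the in-plane
    perpendicular.  comp_id is CLA for chl a, KC2 for chl c.
    """
    d = placement.dipole_direction
    n = placement.plane_normal
    p = np.cross(n, d)  # in-plane perpendicular
    c = placement.center
    r = MG_N_DISTANCE
    atoms = [
        Atom("MG", "Mg", c),
        Atom("NA", "N", c + r * p),
        Atom("NB", "N", c - r * d),
        Atom("NC", "N", c - r * p),
        Atom("ND", "N", c + r * d),
    ]
    comp = "CLA" if placement.kind == "chl_a" else "KC2"
    return Residue(comp_id=comp, chain_id=chain_id, seq_id=seq_id, atoms=atoms,
                   category=placement.kind)


def fe4s4_cluster(center, chain_id: str, seq_id: int, half_edge: float = 1.35) -> Residue:
    """Ideal cubane Fe₄S₄: Fe and S on alternating cube vertices (comp SF4)."""
    center = np.asarray(center, dtype=float)
    atoms = []
    n_fe = n_s = 0
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                corner = center + half_edge * np.array([sx, sy, sz], dtype=float)
                if sx * sy * sz > 0:
                    n_fe += 1
                    atoms.append(Atom(f"FE{n_fe}", "Fe", corner))
                else:
                    n_s += 1
                    atoms.append(Atom(f"S{n_s}", "S", corner))
    return Residue("SF4", chain_id, seq_id, atoms, category="fes_cluster")


def water_residue(position, chain_id: str, seq_id: int) -> Residue:
    return Residue("HOH", chain_id, seq_id, [Atom("O", "O", position)], category="water")


def het_residue(comp_id: str, category: str, center, chain_id: str, seq_id: int) -> Residue:
    """Three-carbon placeholder for carotenoids/lipids/detergents."""
    c = np.asarray(center, dtype=float)
    atoms = [
        Atom("C1", "C", c - np.array([1.0, 0, 0])),
        Atom("C2", "C", c),
        Atom("C3", "C", c + np.array([1.0, 0, 0])),
    ]
    return Residue(comp_id, chain_id, seq_id, atoms, category=category)


def helical_chain(
    chain_id: str,
    n_residues: int,
    start=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    start_seq: int = 1,
    radius: float = 2.3,
    rise: float = 1.5,
    twist_deg: float = 100.0,
) -> list[Residue]:
    """Cα-only α-helical trace; enough geometry for superposition tests."""
    start = np.asarray(start, dtype=float)
    axis = _unit(direction, "direction")
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(axis, ref))
    e2 = np.cross(axis, e1)
    out = []
    for i in range(n_residues):
        ang = math.radians(twist_deg) * i
        pos = start + axis * (rise * i) + radius * (math.cos(ang) * e1 + math.sin(ang) * e2)
        out.append(
            Residue("ALA", chain_id, start_seq + i, [Atom("CA", "C", pos)], category="protein")
        )
    return out


# ---------------------------------------------------------------------------
# declarative toy models

@dataclass
class ToyStructureSpec:
    """Declarative recipe for a small test structure.

    waters entries are either bare positions or ``(cluster_index, radius,
    direction)`` records placing the O at ``radius`` Å from that cluster's
    center along ``direction``.
    """

    chlorophylls: list[ChlPlacement] = field(default_factory=list)
    clusters: list = field(default_factory=list)  # cluster centers
    waters: list = field(default_factory=list)
    protein_chains: list = field(default_factory=list)  # (chain_id, [Cα positions])
    seed: int = 0


def build_toy_model(
    spec: ToyStructureSpec, path: str | Path | None = None, model_id: str = "toy"
) -> StructureModel:
    """Materialize a :class:`ToyStructureSpec`; optionally write mmCIF."""
    residues: list[Residue] = []
    for i, placement in enumerate(spec.chlorophylls):
        residues.append(make_chlorophyll_frame(placement, "P", 101 + i))
    for i, center in enumerate(spec.clusters):
        residues.append(fe4s4_cluster(center, "F", 201 + i))
    for i, w in enumerate(spec.waters):
        # (cluster_index, radius, direction) records have a vector third element
        if (
            isinstance(w, (tuple, list))
            and len(w) == 3
            and isinstance(w[0], (int, np.integer))
            and hasattr(w[2], "__len__")
        ):
            ci, radius, direction = w
            center = np.asarray(spec.clusters[ci], dtype=float)
            pos = center + _unit(np.asarray(direction, float), "water direction") * float(radius)
        else:
            pos = np.asarray(w, dtype=float)
        residues.append(water_residue(pos, "W", 301 + i))
    for chain_id, trace in spec.protein_chains:
        for j, pos in enumerate(trace):
            residues.append(
                Residue("ALA", chain_id, j + 1, [Atom("CA", "C", np.asarray(pos, float))],
                        category="protein")
            )
    model = StructureModel(model_id=model_id, residues=residues).validate()
    if path is not None:
        from .io import write_mmcif

        write_mmcif(model, path)
    return model


# ---------------------------------------------------------------------------
# rigid-transformed copies

def require_proper_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be orthogonal")
    if np.linalg.det(rotation) < 0:
        raise ValueError("improper rotation (det = -1); reflections not allowed")
    return rotation


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transformed_copy(
    model: StructureModel,
    rotation: np.ndarray | None = None,
    translation=(0.0, 0.0, 0.0),
    per_chain_offsets: dict[str, np.ndarray] | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    model_id: str | None = None,
) -> StructureModel:
    """Rigidly transformed deep copy with planted per-chain offsets and noise.

    The global transform x ↦ R x + t is applied to every atom; chains listed
    in ``per_chain_offsets`` are additionally translated (planting known
    subunit shifts); ``noise_sigma`` adds i.i.d. Gaussian noise per coordinate
    with a fixed seed.
    """
    rotation = require_proper_rotation(rotation if rotation is not None else np.eye(3))
    translation = np.asarray(translation, dtype=float)
    offsets = {k: np.asarray(v, dtype=float) for k, v in (per_chain_offsets or {}).items()}
    rng = np.random.default_rng(seed)
    out = model.transformed(rotation, translation, model_id=model_id or model.model_id + "-copy")
    for res in out.residues:
        off = offsets.get(res.chain_id)
        for atom in res.atoms:
            if off is not None:
                atom.position = atom.position + off
            if noise_sigma > 0:
                atom.position = atom.position + rng.normal(0.0, noise_sigma, 3)
    return out


# ---------------------------------------------------------------------------
# placement helpers for the supercomplex stand-ins

def _random_frame(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random orthonormal (dipole, normal) pair."""
    d = _unit(rng.normal(size=3))
    n = rng.normal(size=3)
    n = n - (n @ d) * d
    return d, _unit(n)


def _spread_points(
    n: int,
    rng: np.random.Generator,
    lo,
    hi,
    min_sep: float,
    taken: list[np.ndarray] | None = None,
    exclude: list[tuple[np.ndarray, float]] | None = None,
) -> list[np.ndarray]:
    """Rejection-sample n points with a minimum separation (grid-accelerated)."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    cell = max(min_sep, 1e-6)
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def key(p):
        return tuple((p // cell).astype(int))

    def ok(p):
        kx, ky, kz = key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in grid.get((kx + dx, ky + dy, kz + dz), ()):
                        if np.linalg.norm(p - q) < min_sep:
                            return False
        if exclude:
            for center, radius in exclude:
                if np.linalg.norm(p - center) < radius:
                    return False
        return True

    for p in taken or []:
        grid.setdefault(key(p), []).append(np.asarray(p, float))
    out: list[np.ndarray] = []
    attempts = 0
    while len(out) < n:
        p = rng.uniform(lo, hi)
        attempts += 1
        if attempts > 200 * n + 10000:
            raise RuntimeError("placement sampling failed; box too small for min_sep")
        if ok(p):
            grid.setdefault(key(p), []).append(p)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# PSI-ACPI supercomplex stand-in

#: Cluster centers for F_X, F_A, F_B (stromal side, +z), spaced like the
#: PSI electron-transfer chain (~12–15 Å apart).
_PSI_CLUSTERS = {
    "FX": np.array([0.0, 0.0, 28.0]),
    "FA": np.array([2.0, 10.0, 36.0]),
    "FB": np.array([4.0, 21.0, 41.0]),
}

PSI_CORE_CHAINS = ("A", "B")
PSI_ANTENNA_CHAINS = tuple("abcdefghijklmn")


def psi_supercomplex(seed: int = 0, model_id: str = "psi-acpi-synthetic") -> StructureModel:
    """Synthetic PSI–ACPI supercomplex stand-in (NOT a deposited model).

    Composition mirrors the published cryptophyte PSI–ACPI inventory:
    255 chl a, 20 chl c, 58 alloxanthin, 29 α-carotene, 12 crocoxanthin,
    6 detergent, 44 PG, 17 MGDG, 3 DGDG, 1 SQDG, 422 waters, three Fe₄S₄
    clusters of which 26 waters lie within 8 Å.  Geometry is invented:
    core chains A/B at the center, 14 antenna chains a–n plus the linker s
    on a surrounding ring, PsaC near the clusters, PsaQ on the lumenal side.
    """
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []

    # protein chains: helical Cα traces
    residues += helical_chain("A", 80, start=(-16.0, -6.0, -12.0))
    residues += helical_chain("B", 80, start=(16.0, 6.0, -12.0))
    residues += helical_chain("C", 30, start=(2.0, 8.0, 30.0), direction=(0.3, 1.0, 0.2))
    residues += helical_chain("Q", 24, start=(-6.0, 10.0, -34.0), direction=(1.0, 0.2, 0.0))
    residues += helical_chain("s", 18, start=(48.0, -40.0, -10.0))
    for idx, ch in enumerate(PSI_ANTENNA_CHAINS):
        ang = 2 * math.pi * idx / len(PSI_ANTENNA_CHAINS)
        start = (55.0 * math.cos(ang), 55.0 * math.sin(ang), -14.0)
        residues += helical_chain(ch, 26, start=start)

    # Fe4S4 clusters on chain C
    for i, (name, center) in enumerate(_PSI_CLUSTERS.items()):
        residues.append(fe4s4_cluster(center, "C", 101 + i))
    cluster_centers = list(_PSI_CLUSTERS.values())

    # chlorophyll a blocks: (chain, first seq, count)
    chl_a_blocks = [("A", 801, 45), ("B", 801, 45), ("Q", 302, 1), ("s", 401, 10)]
    for ch in PSI_ANTENNA_CHAINS:
        chl_a_blocks.append((ch, 601 if ch == "c" else 301, 11))
    assert sum(n for _, _, n in chl_a_blocks) == 255

    chl_c_sites = (
        [("d", 312), ("k", 612), ("k", 613), ("n", 612)]
        + [(ch, 621 if ch == "c" else 321) for ch in "abcefghijlm"]
        + [("a", 322), ("b", 322), ("e", 322), ("f", 322), ("g", 322)]
    )
    assert len(chl_c_sites) == 20

    membrane = dict(lo=(-85.0, -85.0, -16.0), hi=(85.0, 85.0, 6.0), min_sep=8.5)
    chain_anchor: dict[str, np.ndarray] = {}
    for ch in ("A", "B", "Q", "s") + PSI_ANTENNA_CHAINS:
        cas = [r.atoms[0].position for r in residues if r.chain_id == ch and r.comp_id == "ALA"]
        chain_anchor[ch] = np.mean(cas, axis=0)

    taken: list[np.ndarray] = []

    def place_near(chain: str, count: int) -> list[np.ndarray]:
        """Pigment centers in a box around the chain's territory."""
        anchor = chain_anchor[chain]
        lo = np.maximum(anchor[:2] - 24.0, -95.0)
        hi = np.minimum(anchor[:2] + 24.0, 95.0)
        pts = _spread_points(
            count, rng,
            (lo[0], lo[1], -16.0), (hi[0], hi[1], 6.0),
            min_sep=membrane["min_sep"], taken=taken,
        )
        taken.extend(pts)
        return pts

    for chain, first_seq, count in chl_a_blocks:
        for j, center in enumerate(place_near(chain, count)):
            d, nrm = _random_frame(rng)
            residues.append(
                make_chlorophyll_frame(
                    ChlPlacement(center, d, nrm, kind="chl_a"), chain, first_seq + j
                )
            )
    for chain, seq in chl_c_sites:
        center = place_near(chain, 1)[0]
        d, nrm = _random_frame(rng)
        residues.append(
            make_chlorophyll_frame(ChlPlacement(center, d, nrm, kind="chl_c"), chain, seq)
        )

    # carotenoids, lipids, detergents: placeholder heteroresidues
    het_plan = [
        ("ALX", "carotenoid", 58, 701),
        ("ACR", "carotenoid", 29, 731),
        ("CRX", "carotenoid", 12, 771),
        ("LHG", "lipid", 44, 501),
        ("LMG", "lipid", 17, 551),
        ("DGD", "lipid", 3, 571),
        ("SQD", "lipid", 1, 581),
        ("LMT", "detergent", 6, 901),
    ]
    chains_cycle = list(PSI_ANTENNA_CHAINS) + ["A", "B"]
    for comp, cat, count, seq0 in het_plan:
        pts = _spread_points(
            count, rng, membrane["lo"], membrane["hi"], min_sep=8.5, taken=taken
        )
        taken.extend(pts)
        for j, p in enumerate(pts):
            chain = chains_cycle[j % len(chains_cycle)]
            residues.append(het_residue(comp, cat, p, chain, seq0 + j // len(chains_cycle)))

    # waters: 26 planted in the Fe–S shell, 396 elsewhere in two layers
    shell_pts = []
    for j in range(26):
        center = cluster_centers[j % 3]
        direction = _unit(rng.normal(size=3))
        radius = rng.uniform(4.6, 7.8)
        shell_pts.append(center + radius * direction)
    # enforce mutual separation among shell waters (resample clashes)
    for j in range(len(shell_pts)):
        tries = 0
        while any(
            np.linalg.norm(shell_pts[j] - shell_pts[k]) < 3.0 for k in range(j)
        ):
            center = cluster_centers[j % 3]
            shell_pts[j] = center + rng.uniform(4.6, 7.8) * _unit(rng.normal(size=3))
            tries += 1
            if tries > 1000:
                raise RuntimeError("could not place shell waters")

    exclude = [(c, 10.5) for c in cluster_centers]
    stromal = _spread_points(
        220, rng, (-45.0, -45.0, 10.0), (45.0, 45.0, 24.0), 3.0, exclude=exclude
    )
    lumenal = _spread_points(
        176, rng, (-45.0, -45.0, -38.0), (45.0, 45.0, -22.0), 3.0, exclude=exclude
    )
    for j, p in enumerate(shell_pts + stromal + lumenal):
        residues.append(water_residue(p, "W", 1001 + j))

    model = StructureModel(model_id=model_id, residues=residues).validate()
    return classify_cofactors(model)


def psi_cluster_sites(model: StructureModel) -> list:
    """Site ids of the three Fe₄S₄ clusters in a PSI stand-in."""
    return [r.site_id for r in model.by_category("fes_cluster")]


def _add_chl_near(
    model: StructureModel,
    anchor_site: tuple[str, int],
    distance: float,
    chain_id: str,
    seq_id: int,
    rng: np.random.Generator,
) -> None:
    """Plant a chl a at an exact Mg–Mg distance from an existing chlorophyll."""
    anchor = model.get(*anchor_site)
    if anchor is None:
        raise ValueError(f"anchor site {anchor_site} not found")
    mg = anchor.atom("MG").position
    direction = _unit(rng.normal(size=3))
    d, nrm = _random_frame(rng)
    res = make_chlorophyll_frame(
        ChlPlacement(mg + distance * direction, d, nrm, kind="chl_a"), chain_id, seq_id
    )
    model.residues.append(res)


def rsalina_psi_variant(
    reference: StructureModel, seed: int = 1, model_id: str = "psi-rsalina-synthetic"
) -> StructureModel:
    """Stand-in for the *R. salina* PSI–ACPI model, derived from the reference.

    Planted differences, following the published comparison: antenna chain k
    translated 3.2 Å (core-anchored); an extra chl a303/Q at 17.9 Å from
    a306/i; an extra chl a855/A at 12.5 Å from a606/c.  A small coordinate
    noise (σ = 0.05 Å) emulates independent model building.  Synthetic.
    """
    rng = np.random.default_rng(seed)
    shift_dir = _unit(np.array([0.6, -0.7, 0.15]))
    out = transformed_copy(
        reference,
        rotation=random_rotation(rng),
        translation=rng.uniform(-20, 20, 3),
        per_chain_offsets={"k": 3.2 * shift_dir},
        noise_sigma=0.05,
        seed=int(rng.integers(2**31)),
        model_id=model_id,
    )
    _add_chl_near(out, ("i", 306), 17.9, "Q", 303, rng)
    _add_chl_near(out, ("c", 606), 12.5, "A", 855, rng)
    return classify_cofactors(out.validate())


def cplacoidea_psi_variant(
    reference: StructureModel, seed: int = 2, model_id: str = "psi-cplacoidea-synthetic"
) -> StructureModel:
    """Stand-in for the *C. placoidea* PSI–ACPI model.

    Plants 10 differing chlorophyll binding sites against the reference:
    5 chl a sites re-assigned as chl c, 3 chl c sites re-assigned as chl a,
    one chl c site deleted (c613/k) and one extra chl a (a614/9 analogue,
    chain n seq 614); antenna chain k translated 1.1 Å.  Synthetic.
    """
    rng = np.random.default_rng(seed)
    out = transformed_copy(
        reference,
        rotation=random_rotation(rng),
        translation=rng.uniform(-20, 20, 3),
        per_chain_offsets={"k": 1.1 * _unit(np.array([0.2, 0.9, -0.1]))},
        noise_sigma=0.05,
        seed=int(rng.integers(2**31)),
        model_id=model_id,
    )
    a_to_c = [("a", 306), ("b", 310), ("e", 305), ("l", 307), ("j", 307)]
    c_to_a = [("d", 312), ("k", 612), ("n", 612)]
    for chain, seq in a_to_c:
        res = out.get(chain, seq)
        res.comp_id, res.category = "KC2", "chl_c"
    for chain, seq in c_to_a:
        res = out.get(chain, seq)
        res.comp_id, res.category = "CLA", "chl_a"
    out.residues = [r for r in out.residues if r.site_id != ("k", 613, "KC2")]
    anchor = out.get("n", 301)
    mg = anchor.atom("MG").position
    d, nrm = _random_frame(rng)
    out.residues.append(
        make_chlorophyll_frame(
            ChlPlacement(mg + 9.0 * _unit(rng.normal(size=3)), d, nrm, "chl_a"), "n", 614
        )
    )
    return classify_cofactors(out.validate())


def conservation_variant(
    reference: StructureModel,
    shell_water_sites: list,
    conserved_indices: list[int],
    seed: int = 3,
    model_id: str = "psi-conservation-synthetic",
    jitter: float = 0.25,
    n_decoys: int = 40,
) -> StructureModel:
    """Comparison-model stand-in for water-conservation analysis.

    Copies the reference protein core (chains A, B, C) and clusters, keeps the
    shell waters at ``conserved_indices`` (jittered by up to ``jitter`` Å, well
    inside the match radius), drops the rest, adds decoy waters far from the
    shell, and applies a random rigid transform.  Emulates e.g. a
    cyanobacterial or plant PSI around the Fe–S clusters.  Synthetic.
    """
    rng = np.random.default_rng(seed)
    keep_chains = {"A", "B", "C"}
    residues = []
    for res in reference.residues:
        if res.chain_id in keep_chains and res.category in ("protein", "fes_cluster"):
            residues.append(
                Residue(res.comp_id, res.chain_id, res.seq_id,
                        [Atom(a.name, a.element, a.position.copy()) for a in res.atoms],
                        category=res.category)
            )
    shell_positions = []
    for site in shell_water_sites:
        res = reference.get(site[0], site[1])
        shell_positions.append(res.atoms[0].position)
    for j, idx in enumerate(sorted(conserved_indices)):
        p = shell_positions[idx] + rng.uniform(-1, 1, 3) * jitter / math.sqrt(3)
        residues.append(water_residue(p, "W", 2001 + j))
    exclude = [(p, 4.0) for p in shell_positions]
    decoys = _spread_points(
        n_decoys, rng, (-40.0, -40.0, 8.0), (40.0, 40.0, 50.0), 3.0, exclude=exclude
    )
    for j, p in enumerate(decoys):
        residues.append(water_residue(p, "W", 3001 + j))
    model = StructureModel(model_id=model_id, residues=residues).validate()
    model = transformed_copy(
        model,
        rotation=random_rotation(rng),
        translation=rng.uniform(-15, 15, 3),
        noise_sigma=0.02,
        seed=int(rng.integers(2**31)),
        model_id=model_id,
    )
    return classify_cofactors(model.validate())


# ---------------------------------------------------------------------------
# PSII-ACPII supercomplex stand-in

PSII_CORE_CHAINS = ("A", "D", "C", "B")  # D1, D2, CP43, CP47
PSII_ANTENNA_CHAINS = tuple("123456")


def psii_supercomplex(seed: int = 0, model_id: str = "psii-acpii-synthetic") -> StructureModel:
    """Synthetic PSII–ACPII supercomplex stand-in (NOT a deposited model).

    Composition mirrors the published cryptophyte PSII–ACPII inventory:
    194 chl a, 22 chl c, 46 alloxanthin, 24 α-carotene, 8 crocoxanthin,
    18 PG, 22 MGDG, 4 DGDG, 4 SQDG, 676 waters; no Mn₄CaO₅ cluster (the
    stationary-phase form lacks the oxygen-evolving complex).
    """
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    core_starts = {"A": (-18.0, -8.0, -12.0), "D": (18.0, 8.0, -12.0),
                   "C": (-18.0, 12.0, -12.0), "B": (18.0, -12.0, -12.0)}
    for ch, start in core_starts.items():
        residues += helical_chain(ch, 70, start=start)
    residues += helical_chain("g", 20, start=(40.0, 0.0, -12.0))
    for idx, ch in enumerate(PSII_ANTENNA_CHAINS):
        ang = 2 * math.pi * idx / 6
        residues += helical_chain(
            ch, 26, start=(50.0 * math.cos(ang), 50.0 * math.sin(ang), -14.0)
        )

    taken: list[np.ndarray] = []

    def sample(count):
        pts = _spread_points(
            count, rng, (-70.0, -70.0, -16.0), (70.0, 70.0, 6.0), 8.5, taken=taken
        )
        taken.extend(pts)
        return pts

    chl_a_blocks = [("A", 401, 35), ("D", 401, 35), ("B", 601, 30), ("C", 601, 30),
                    ("g", 301, 4)] + [(ch, 301, 10) for ch in PSII_ANTENNA_CHAINS]
    assert sum(n for _, _, n in chl_a_blocks) == 194
    for chain, seq0, count in chl_a_blocks:
        for j, p in enumerate(sample(count)):
            d, nrm = _random_frame(rng)
            residues.append(
                make_chlorophyll_frame(ChlPlacement(p, d, nrm, "chl_a"), chain, seq0 + j)
            )
    # 22 chl c: 3 per antenna chain plus 4 on the linker
    for chain, seq0, count in [(ch, 331, 3) for ch in PSII_ANTENNA_CHAINS] + [("g", 351, 4)]:
        for j, p in enumerate(sample(count)):
            d, nrm = _random_frame(rng)
            residues.append(
                make_chlorophyll_frame(ChlPlacement(p, d, nrm, "chl_c"), chain, seq0 + j)
            )

    het_plan = [
        ("ALX", "carotenoid", 46, 701),
        ("ACR", "carotenoid", 24, 741),
        ("CRX", "carotenoid", 8, 771),
        ("LHG", "lipid", 18, 501),
        ("LMG", "lipid", 22, 531),
        ("DGD", "lipid", 4, 561),
        ("SQD", "lipid", 4, 571),
    ]
    chains_cycle = list(PSII_ANTENNA_CHAINS) + ["A", "B", "C", "D"]
    for comp, cat, count, seq0 in het_plan:
        for j, p in enumerate(sample(count)):
            chain = chains_cycle[j % len(chains_cycle)]
            residues.append(het_residue(comp, cat, p, chain, seq0 + j // len(chains_cycle)))

    lum = _spread_points(400, rng, (-55.0, -55.0, -40.0), (55.0, 55.0, -22.0), 3.0)
    strom = _spread_points(276, rng, (-55.0, -55.0, 10.0), (55.0, 55.0, 26.0), 3.0)
    for j, p in enumerate(lum + strom):
        residues.append(water_residue(p, "W", 1001 + j))

    model = StructureModel(model_id=model_id, residues=residues).validate()
    return classify_cofactors(model)
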