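"""Reading, writing and inventorying coordinate models.

mmCIF (PDBx) and legacy PDB files are parsed with gemmi (gzip-transparent) and
converted to the light-weight :class:`~chlorofret.model.StructureModel`
container.  Alternate locations are resolved to a single conformer per atom:
the highest occupancy wins, ties go to the lexicographically first alt_id, so
downstream geometry is deterministic.  Author chain identifiers and residue
numbers are kept as the canonical site labels (structure papers name sites in
author style, e.g. ``a306/i``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import pandas as pd

from .components import ComponentMap, classify_cofactors
from .fret import Chlorophyll
from .model import Atom, Residue, SiteId, StructureModel

logger = logging.getLogger(__name__)

_FORMATS = {
    "auto": gemmi.CoorFormat.Detect,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "pdb": gemmi.CoorFormat.Pdb,
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed or is empty."""


def read_structure(
    path: str | Path,
    format: str = "auto",
    model_id: str | None = None,
    classify: bool = True,
    component_map: ComponentMap | None = None,
) -> StructureModel:
    """Read a coordinate file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        mmCIF or PDB file, optionally gzipped.
    format:
        ``auto`` (extension-based detection), ``mmcif`` or ``pdb``.
    model_id:
        Identifier for the returned model; defaults to the file stem.
    classify:
        Assign cofactor categories immediately (default).

    Atoms with zero occupancy are dropped; for alternate locations the
    highest-occupancy conformer is kept (ties: first alt_id alphabetically).
    Only the first model of multi-model files is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no models")

    residues: list[Residue] = []
    for chain in st[0]:
        for res in chain:
            atoms = _resolve_altlocs(res)
            if not atoms:
                continue
            residues.append(
                Residue(
                    comp_id=res.name,
                    chain_id=chain.name,
                    seq_id=res.seqid.num,
                    atoms=atoms,
                )
            )
    if not residues:
        raise StructureParseError(f"{path}: model contains no atoms")

    model = StructureModel(
        model_id=model_id or path.name.split(".")[0],
        residues=residues,
        source_format="pdb" if _looks_like_pdb(path, format) else "mmcif",
    ).validate()
    if classify:
        classify_cofactors(model, component_map)
    return model


def _looks_like_pdb(path: Path, format: str) -> bool:
    if format == "pdb":
        return True
    if format == "mmcif":
        return False
    suffixes = [s.lower() for s in path.suffixes]
    return ".pdb" in suffixes or ".ent" in suffixes


def _resolve_altlocs(res: gemmi.Residue) -> list[Atom]:
    """One Atom per atom name: drop zero occupancy, keep best conformer."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        if a.occ <= 0.0:
            continue
        by_name.setdefault(a.name, []).append(a)
    out: list[Atom] = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occ, _alt(a)))
        out.append(
            Atom(
                name=name,
                element=best.element.name,
                position=[best.pos.x, best.pos.y, best.pos.z],
                occupancy=min(best.occ, 1.0),
                alt_id=_alt(best),
            )
        )
    return out


def _alt(a: gemmi.Atom) -> str:
    return a.altloc.replace("\x00", "").strip()


# ---------------------------------------------------------------------------
# writing

def to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in model.residues:
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
        gr = gemmi.Residue()
        gr.name = res.comp_id
        gr.seqid = gemmi.SeqId(res.seq_id, " ")
        gr.het_flag = "A" if res.category == "protein" else "H"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = atom.occupancy
            if atom.alt_id:
                ga.altloc = atom.alt_id
            gr.add_atom(ga)
        chains[res.chain_id].add_residue(gr)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_mmcif(model: StructureModel, path: str | Path) -> Path:
    """Serialize a model to mmCIF, re-readable by :func:`read_structure`."""
    path = Path(path)
    to_gemmi(model).make_mmcif_document().write_file(str(path))
    return path


def write_pdb(model: StructureModel, path: str | Path) -> Path:
    path = Path(path)
    to_gemmi(model).write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# inventories

@dataclass
class CofactorInventory:
    """Per-category residue counts plus the underlying site table."""

    model_id: str
    counts: dict[str, int]
    by_site: list[tuple[str, int, str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.model_id, cat, n) for cat, n in sorted(self.counts.items())],
            columns=["model_id", "category", "count"],
        )

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.by_site, columns=["chain_id", "seq_id", "comp_id", "category"]
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def sites_to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.site_frame().to_csv(path, index=False)
        return path


def inventory(model: StructureModel) -> CofactorInventory:
    """Count residues per cofactor category (waters count one per residue)."""
    counts: dict[str, int] = {}
    sites = []
    for res in model.residues:
        counts[res.category] = counts.get(res.category, 0) + 1
        sites.append((res.chain_id, res.seq_id, res.comp_id, res.category))
    sites.sort(key=lambda s: (s[0], s[1]))
    return CofactorInventory(model_id=model.model_id, counts=counts, by_site=sites)


# ---------------------------------------------------------------------------
# chlorophyll extraction

def extract_chlorophylls(
    model: StructureModel,
) -> tuple[list[Chlorophyll], list[SiteId]]:
    """Build :class:`Chlorophyll` records from classified chl residues.

    Requires the central magnesium (``MG``) and the two pyrrole nitrogens
    ``NB`` and ``ND`` whose connecting vector approximates the Qy transition
    dipole.  Residues missing any of the three atoms are excluded and returned
    in the second element.
    """
    chls: list[Chlorophyll] = []
    excluded: list[SiteId] = []
    for res in model.by_category("chl_a", "chl_c"):
        mg, nb, nd = res.atom("MG"), res.atom("NB"), res.atom("ND")
        if mg is None or nb is None or nd is None:
            excluded.append(res.site_id)
            continue
        chls.append(
            Chlorophyll(
                site_id=res.site_id,
                kind=res.category,
                mg=mg.position,
                nb=nb.position,
                nd=nd.position,
            )
        )
    if excluded:
        logger.warning(
            "model %s: %d chlorophyll residue(s) lack MG/NB/ND and were excluded: %s",
            model.model_id,
            len(excluded),
            ", ".join(f"{c}:{s}" for c, s, _ in excluded),
        )
    return chls, excluded
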