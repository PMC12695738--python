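"""Core coordinate-model containers.

A :class:`StructureModel` is a flat list of residues with author-style chain
identifiers and residue numbers, which is how sites are named in the
photosynthesis literature (e.g. chlorophyll ``a306/i`` is seq 306 on antenna
chain ``i``).  Parsing from mmCIF/PDB lives in :mod:`chlorofret.io`; category
assignment lives in :mod:`chlorofret.components`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

#: Recognized cofactor categories.
CATEGORIES = (
    "protein",
    "chl_a",
    "chl_c",
    "carotenoid",
    "lipid",
    "water",
    "fes_cluster",
    "ion",
    "detergent",
    "unknown",
)

SiteId = tuple[str, int, str]  # (chain_id, seq_id, comp_id)


@dataclass
class Atom:
    """A single atom with author atom name and Cartesian position in Å."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    alt_id: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue / heteroresidue identified by author chain and number."""

    comp_id: str
    chain_id: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    category: str = "unknown"

    @property
    def site_id(self) -> SiteId:
        return (self.chain_id, self.seq_id, self.comp_id)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def center(self) -> np.ndarray:
        """Geometric center of heavy atoms (all atoms if only hydrogens)."""
        atoms = self.heavy_atoms() or self.atoms
        return np.mean([a.position for a in atoms], axis=0)


@dataclass
class StructureModel:
    """A parsed coordinate model: an ordered list of residues.

    ``(chain_id, seq_id, comp_id)`` triples are unique after alternate-location
    resolution; :meth:`validate` enforces this.
    """

    model_id: str
    residues: list[Residue] = field(default_factory=list)
    source_format: str = "synthetic"

    def validate(self) -> "StructureModel":
        seen: set[SiteId] = set()
        for r in self.residues:
            if r.site_id in seen:
                raise ValueError(f"duplicate residue site {r.site_id} in model {self.model_id!r}")
            seen.add(r.site_id)
        return self

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def by_category(self, *categories: str) -> list[Residue]:
        want = set(categories)
        return [r for r in self.residues if r.category in want]

    def get(self, chain_id: str, seq_id: int) -> Residue | None:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_id == seq_id:
                return r
        return None

    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def transformed(
        self, rotation: np.ndarray, translation: np.ndarray, model_id: str | None = None
    ) -> "StructureModel":
        """Return a rigidly transformed deep copy: x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = []
        for r in self.residues:
            atoms = [replace(a, position=rotation @ a.position + translation) for a in r.atoms]
            out.append(replace(r, atoms=atoms))
        return StructureModel(
            model_id=model_id or self.model_id,
            residues=out,
            source_format=self.source_format,
        )

    def coords(self, atom_names: Iterable[str] | None = None) -> np.ndarray:
        """(n, 3) array of atom positions, optionally restricted by atom name."""
        names = set(atom_names) if atom_names is not None else None
        pts = [
            a.position
            for r in self.residues
            for a in r.atoms
            if names is None or a.name in names
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)
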