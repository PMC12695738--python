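"""Chemical-component classification.

Categories are assigned from the component code (``comp_id``) alone, through a
:class:`ComponentMap`.  The default map ships as package data
(``data/components.yaml``) and covers the pigment, lipid, cluster and
detergent codes common in photosystem depositions; standard amino acids and
nucleotides are recognized programmatically.  Codes absent from the map fall
back to ``unknown`` — never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .model import CATEGORIES, StructureModel

logger = logging.getLogger(__name__)

STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE SEC PYL UNK""".split()
)
STANDARD_NUCLEOTIDES = frozenset("A C G U DA DC DG DT DU N".split())


def _parse_entry(comp_id: str, value: str) -> tuple[str, str]:
    if ":" in value:
        category, display = value.split(":", 1)
    else:
        category, display = value, comp_id
    category = category.strip()
    if category not in CATEGORIES:
        raise ValueError(f"component {comp_id!r}: unknown category {category!r}")
    return category, display.strip()


@dataclass
class ComponentMap:
    """Total mapping comp_id -> (category, display_name), ``unknown`` fallback."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    provenance: str = "builtin-default"

    @classmethod
    def default(cls) -> "ComponentMap":
        text = resources.files("chlorofret.data").joinpath("components.yaml").read_text()
        raw = yaml.safe_load(text)
        entries = {str(k): _parse_entry(str(k), str(v)) for k, v in raw.items()}
        return cls(entries=entries, provenance="builtin-default")

    @classmethod
    def from_file(cls, path: str | Path, base: "ComponentMap | None" = None) -> "ComponentMap":
        """Load a user map; entries override the base (default) map per key."""
        base = base if base is not None else cls.default()
        raw = yaml.safe_load(Path(path).read_text()) or {}
        entries = dict(base.entries)
        entries.update({str(k): _parse_entry(str(k), str(v)) for k, v in raw.items()})
        return cls(entries=entries, provenance=str(path))

    def category(self, comp_id: str) -> str:
        if comp_id in self.entries:
            return self.entries[comp_id][0]
        if comp_id in STANDARD_AMINO_ACIDS or comp_id in STANDARD_NUCLEOTIDES:
            return "protein"
        return "unknown"

    def display_name(self, comp_id: str) -> str:
        if comp_id in self.entries:
            return self.entries[comp_id][1]
        return comp_id


def classify_cofactors(model: StructureModel, cmap: ComponentMap | None = None) -> StructureModel:
    """Assign every residue's category from its comp_id (in place; returns model).

    Unknown codes are categorized as ``unknown`` and reported via logging,
    never dropped.
    """
    cmap = cmap if cmap is not None else ComponentMap.default()
    unknown: set[str] = set()
    for res in model.residues:
        res.category = cmap.category(res.comp_id)
        if res.category == "unknown":
            unknown.add(res.comp_id)
    if unknown:
        logger.warning(
            "model %s: %d component code(s) not in the component map, "
            "classified as unknown: %s",
            model.model_id,
            len(unknown),
            ", ".join(sorted(unknown)),
        )
    return model
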