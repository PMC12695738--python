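"""Water shells around target cofactors and their cross-structure conservation.

PSI's electron-transfer chain ends in three Fe₄S₄ clusters (F_X, F_A, F_B)
that sit in a hydrated cavity on the stromal side.  ``water_shell`` collects
the water oxygens within a radius of the clusters (default 8 Å, inclusive,
measured to the nearest cluster atom); ``conserved_waters`` asks, after a
rigid superposition, which of those waters have a counterpart within a match
radius in another structure — e.g. a cyanobacterial or plant photosystem.
The match radius (default 1.2 Å, roughly the positional uncertainty of an
ordered water at ~2 Å resolution) is deliberately exposed: conservation
counts depend on it, and ``conservation_summary`` supports sweeping it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .compare import SuperpositionResult
from .model import Residue, SiteId, StructureModel


@dataclass
class HydrationParameters:
    shell_radius: float = 8.0  # Å, inclusive
    match_radius: float = 1.2  # Å, inclusive
    distance_reference: str = "any_cluster_atom"  # or "cluster_centroid"

    def __post_init__(self):
        if self.shell_radius <= 0 or self.match_radius <= 0:
            raise ValueError("radii must be positive")
        if self.distance_reference not in ("any_cluster_atom", "cluster_centroid"):
            raise ValueError(f"unknown distance_reference {self.distance_reference!r}")


def _water_oxygen(res: Residue) -> np.ndarray | None:
    for a in res.atoms:
        if a.element.upper() == "O" or a.name.startswith("O"):
            return a.position
    return None


def _model_waters(model: StructureModel) -> tuple[list[SiteId], np.ndarray]:
    sites, pos = [], []
    for res in model.by_category("water"):
        o = _water_oxygen(res)
        if o is not None:
            sites.append(res.site_id)
            pos.append(o)
    return sites, np.asarray(pos, dtype=float).reshape(-1, 3)


@dataclass
class ShellWater:
    site_id: SiteId
    position: np.ndarray  # O atom, Å
    min_distance: float  # Å to the target reference


@dataclass
class WaterShell:
    model_id: str
    targets: list[SiteId]
    waters: list[ShellWater]
    shell_radius: float

    def __len__(self) -> int:
        return len(self.waters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model_id": self.model_id,
                    "water_chain": w.site_id[0],
                    "water_seq": w.site_id[1],
                    "min_dist_A": w.min_distance,
                }
                for w in self.waters
            ],
            columns=["model_id", "water_chain", "water_seq", "min_dist_A"],
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def water_shell(
    model: StructureModel,
    targets: Sequence[SiteId] | Sequence[Residue],
    params: HydrationParameters | None = None,
) -> WaterShell:
    """Waters whose O atom lies within ``shell_radius`` (inclusive) of the targets.

    ``targets`` are residues or site ids (e.g. the three Fe–S clusters); the
    distance reference is the nearest heavy atom of any target by default, or
    per-target centroids with ``distance_reference="cluster_centroid"``.
    Result is sorted by min distance.
    """
    params = params if params is not None else HydrationParameters()
    target_res: list[Residue] = []
    for t in targets:
        if isinstance(t, Residue):
            res = t
        else:
            chain, seq = t[0], t[1]
            res = model.get(chain, seq)
            if res is None:
                raise ValueError(f"target site {t} not found in model {model.model_id!r}")
        target_res.append(res)
    if not target_res:
        raise ValueError("no target residues given")

    if params.distance_reference == "cluster_centroid":
        ref_pts = np.array([r.center() for r in target_res])
    else:
        ref_pts = np.array(
            [a.position for r in target_res for a in r.heavy_atoms()]
        ).reshape(-1, 3)
    tree = cKDTree(ref_pts)

    sites, pos = _model_waters(model)
    waters = []
    if len(sites):
        dmin, _ = tree.query(pos)
        for s, p, d in zip(sites, pos, dmin):
            if d <= params.shell_radius:
                waters.append(ShellWater(s, p, float(d)))
    waters.sort(key=lambda w: (w.min_distance, w.site_id))
    return WaterShell(
        model_id=model.model_id,
        targets=[r.site_id for r in target_res],
        waters=waters,
        shell_radius=params.shell_radius,
    )


@dataclass
class ConservationRecord:
    """Whether one reference shell water has a counterpart in another model."""

    water: SiteId
    comparison_model: str
    conserved: bool
    nearest_water: SiteId | None
    distance: float  # Å; inf when the other model has no waters


def conserved_waters(
    shell_ref: WaterShell,
    other: StructureModel,
    superposition: SuperpositionResult | None = None,
    params: HydrationParameters | None = None,
) -> list[ConservationRecord]:
    """Match reference shell waters to waters of ``other`` after superposition.

    ``superposition`` maps ``other`` onto the reference frame (identity if
    omitted).  Matching is greedy nearest-first and one-to-one: each water of
    ``other`` can answer for at most one reference water; ties break on site
    ids.  A reference water is conserved when its match lies within
    ``match_radius`` (inclusive).
    """
    params = params if params is not None else HydrationParameters()
    superposition = superposition if superposition is not None else SuperpositionResult.identity()
    sites_o, pos_o = _model_waters(other)
    records: dict[SiteId, ConservationRecord] = {
        w.site_id: ConservationRecord(w.site_id, other.model_id, False, None, np.inf)
        for w in shell_ref.waters
    }
    if not len(sites_o):
        import logging

        logging.getLogger(__name__).warning(
            "model %s contains no waters; nothing conserved", other.model_id
        )
        return [records[w.site_id] for w in shell_ref.waters]

    pos_o = superposition.apply(pos_o)
    candidates = []
    for w in shell_ref.waters:
        d = np.linalg.norm(pos_o - w.position, axis=1)
        for j in np.flatnonzero(d <= params.match_radius):
            candidates.append((float(d[j]), w.site_id, sites_o[j]))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_ref: set[SiteId] = set()
    used_other: set[SiteId] = set()
    for d, sref, sother in candidates:
        if sref in used_ref or sother in used_other:
            continue
        records[sref] = ConservationRecord(sref, other.model_id, True, sother, d)
        used_ref.add(sref)
        used_other.add(sother)
    return [records[w.site_id] for w in shell_ref.waters]


def conservation_summary(
    records_by_model: dict[str, Iterable[ConservationRecord]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate records from several comparison models.

    Returns ``(per_model, per_water)``: conserved counts per comparison model,
    and for each reference water the number of models in which it is conserved.
    """
    per_model_rows = []
    per_water: dict[SiteId, int] = {}
    for model_id, records in records_by_model.items():
        records = list(records)
        per_model_rows.append(
            {
                "comparison_model": model_id,
                "n_conserved": sum(r.conserved for r in records),
                "n_waters": len(records),
            }
        )
        for r in records:
            per_water[r.water] = per_water.get(r.water, 0) + int(r.conserved)
    per_model = pd.DataFrame(
        per_model_rows, columns=["comparison_model", "n_conserved", "n_waters"]
    )
    per_water_df = pd.DataFrame(
        [
            {"water_chain": s[0], "water_seq": s[1], "n_models_conserved": n}
            for s, n in sorted(per_water.items())
        ],
        columns=["water_chain", "water_seq", "n_models_conserved"],
    )
    return per_model, per_water_df


def conservation_to_frame(records: Iterable[ConservationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "water_chain": r.water[0],
                "water_seq": r.water[1],
                "comparison_model": r.comparison_model,
                "conserved": r.conserved,
                "nearest_dist_A": r.distance,
            }
            for r in records
        ],
        columns=["water_chain", "water_seq", "comparison_model", "conserved", "nearest_dist_A"],
    )
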