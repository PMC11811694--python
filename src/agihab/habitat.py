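"""3-D species habitat masks and the species registry.

A species' contemporary habitat is built in three steps: threshold its 2-D
occurrence-probability (or squid habitat-suitability) map, regrid the boolean
map to the analysis grid by largest area fraction, and extrude it over the
species' depth range.  The registry bundles the resulting records; the
packaged species table carries the study set of one predator (Antarctic
toothfish) and 28 prey with their depth ranges and published thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .grid import DOMAIN_DEPTH_MAX, OceanGrid

__all__ = [
    "SpeciesRecord",
    "SpeciesRegistry",
    "threshold_probability",
    "threshold_suitability",
    "regrid_largest_area_fraction",
    "extrude_depth",
    "build_habitat3d",
    "load_species_table",
    "load_registry",
]

log = logging.getLogger(__name__)


@dataclass
class SpeciesRecord:
    """One species: identity, depth range, probability map and 3-D habitat."""

    species_id: int
    name: str
    common_name: str = ""
    min_depth: float = 0.0
    max_depth: float = 0.0
    prob_map: Optional[np.ndarray] = None
    suitability_threshold: Optional[float] = None
    habitat3d: Optional[np.ndarray] = None
    thresholds: Optional[object] = None  # SpeciesThresholds, filled by the pipeline

    def __post_init__(self):
        if not (0 <= self.min_depth < self.max_depth):
            raise ValueError(
                f"species {self.species_id}: need 0 <= min_depth < max_depth, "
                f"got [{self.min_depth}, {self.max_depth}]"
            )

    @property
    def is_squid(self) -> bool:
        return self.suitability_threshold is not None


@dataclass
class SpeciesRegistry:
    """Ordered species collection; the predator is the record with predator_id."""

    records: List[SpeciesRecord] = field(default_factory=list)
    predator_id: int = 1

    def __post_init__(self):
        ids = [r.species_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids: {dupes}")
        if self.records and self.predator_id not in ids:
            raise ValueError(f"predator id {self.predator_id} not in registry")

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def get(self, species_id: int) -> SpeciesRecord:
        for r in self.records:
            if r.species_id == species_id:
                return r
        raise KeyError(species_id)

    @property
    def predator(self) -> SpeciesRecord:
        return self.get(self.predator_id)

    @property
    def prey(self) -> List[SpeciesRecord]:
        return [r for r in self.records if r.species_id != self.predator_id]


def threshold_probability(prob_map: np.ndarray, threshold: float) -> np.ndarray:
    """Occurrence mask from a probability map.

    Threshold 0 means "any non-zero probability" (strictly > 0); a positive
    threshold is inclusive (p >= threshold), so a printed threshold value of
    0.8 keeps cells at exactly 0.8.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    prob_map = np.asarray(prob_map, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((prob_map < 0) | (prob_map > 1)):
            raise ValueError("probabilities outside [0, 1]")
        if threshold == 0.0:
            return prob_map > 0.0
        return prob_map >= threshold


def threshold_suitability(suit_map: np.ndarray, species_threshold: float) -> np.ndarray:
    """Squid habitat mask: suitability >= the species' published threshold."""
    suit_map = np.asarray(suit_map, dtype=float)
    with np.errstate(invalid="ignore"):
        return suit_map >= species_threshold


def _overlap_matrix(tgt_bounds: np.ndarray, src_bounds: np.ndarray, transform=None) -> np.ndarray:
    """(n_tgt, n_src) matrix of 1-D interval overlap lengths.

    ``transform`` maps bound coordinates before measuring length (sin of
    latitude gives exact spherical band weights).
    """
    t = np.asarray(tgt_bounds, dtype=float)
    s = np.asarray(src_bounds, dtype=float)
    if transform is not None:
        t, s = transform(t), transform(s)
    lo = np.maximum(t[:-1, None], s[None, :-1])
    hi = np.minimum(t[1:, None], s[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def regrid_largest_area_fraction(
    mask: np.ndarray,
    src_lat_bounds: np.ndarray,
    src_lon_bounds: np.ndarray,
    target: OceanGrid,
) -> np.ndarray:
    """Regrid a boolean (lat, lon) mask to the target grid by largest area fraction.

    Each target cell takes the categorical value (0/1) covering the larger
    fraction of its overlapped area; exact 50/50 ties resolve to presence.
    Areas use the spherical approximation dA = R^2 cos(phi) dphi dlambda,
    computed exactly per lat band via sin(phi) differences.
    """
    mask = np.asarray(mask, dtype=float)
    a_lat = _overlap_matrix(
        target.lat_bounds, src_lat_bounds, transform=lambda b: np.sin(np.deg2rad(b))
    )
    a_lon = _overlap_matrix(target.lon_bounds, src_lon_bounds)
    covered = a_lat @ np.ones_like(mask) @ a_lon.T
    if not np.any(covered > 0):
        raise ValueError("source and target grids do not overlap")
    present = a_lat @ mask @ a_lon.T
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(covered > 0, present / np.where(covered > 0, covered, 1.0), 0.0)
    return frac >= 0.5


def extrude_depth(
    mask2d: np.ndarray, min_depth: float, max_depth: float, grid: OceanGrid
) -> np.ndarray:
    """Extend a 2-D mask over [min_depth, max_depth]: levels by centre, wet cells only.

    A level belongs to the range iff its centre lies in the closed interval;
    the result is intersected with the wet mask and the 3185 m analysis cap.
    """
    if not min_depth < max_depth:
        raise ValueError("min_depth must be below max_depth")
    z = grid.depth_centers
    in_range = (z >= min_depth) & (z <= max_depth) & (z <= DOMAIN_DEPTH_MAX)
    if not in_range.any():
        log.warning(
            "no depth level centre in range [%s, %s] m; habitat mask is empty",
            min_depth,
            max_depth,
        )
    return in_range[:, None, None] & np.asarray(mask2d, bool)[None, :, :] & grid.wet_mask


def build_habitat3d(
    record: SpeciesRecord,
    grid: OceanGrid,
    probability_threshold: float = 0.0,
    src_lat_bounds: Optional[np.ndarray] = None,
    src_lon_bounds: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Threshold, (optionally) regrid, and extrude one species' 2-D map.

    Squid records use their fixed suitability threshold; everything else uses
    ``probability_threshold``.  If source bounds are given the thresholded
    mask is regridded by largest area fraction first, and the fraction of
    presence lost outside the analysis grid is logged.
    """
    if record.prob_map is None:
        raise ValueError(f"species {record.species_id} has no probability map")
    if record.is_squid:
        mask2d = threshold_suitability(record.prob_map, record.suitability_threshold)
    else:
        mask2d = threshold_probability(record.prob_map, probability_threshold)
    if src_lat_bounds is not None and src_lon_bounds is not None:
        src_present = int(mask2d.sum())
        overlap_rows = (
            _overlap_matrix(
                src_lat_bounds, grid.lat_bounds, transform=lambda b: np.sin(np.deg2rad(b))
            ).sum(axis=1)
            > 0
        )
        truncated = int(mask2d[~overlap_rows, :].sum()) if src_present else 0
        if truncated:
            log.info(
                "species %s: %.1f%% of source presence cells lie outside the "
                "analysis grid and are truncated",
                record.species_id,
                100.0 * truncated / src_present,
            )
        mask2d = regrid_largest_area_fraction(mask2d, src_lat_bounds, src_lon_bounds, grid)
    return extrude_depth(mask2d, record.min_depth, record.max_depth, grid)


# ---------------------------------------------------------------------------
# species table / registry loading
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "species_id",
    "name",
    "common_name",
    "min_depth_m",
    "max_depth_m",
    "suitability_threshold",
    "source",
]


def load_species_table(path=None) -> pd.DataFrame:
    """Load the species characteristics table (packaged study fixture by default).

    Columns include identity, depth range, the squid suitability thresholds,
    and the published Tpref / pO2_thr / AGI_crit at occurrence-probability
    thresholds 0 and 0.8 (columns suffixed ``_p08``).
    """
    if path is None:
        src = resources.files("agihab") / "data" / "species_table.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species table missing columns: {missing}")
    return df


def load_registry(
    table: pd.DataFrame,
    prob_maps: Dict[int, np.ndarray],
    grid: OceanGrid,
    probability_threshold: float = 0.0,
    predator_id: int = 1,
    src_lat_bounds: Optional[np.ndarray] = None,
    src_lon_bounds: Optional[np.ndarray] = None,
) -> SpeciesRegistry:
    """Build a registry with 3-D habitats from a species table and 2-D maps.

    ``prob_maps`` maps species_id to its (lat, lon) probability/suitability
    array; a species without a map raises.
    """
    records = []
    for _, row in table.iterrows():
        sid = int(row["species_id"])
        if sid not in prob_maps:
            raise ValueError(f"missing probability map for species {sid} ({row['name']})")
        suit = row.get("suitability_threshold")
        suit = None if pd.isna(suit) else float(suit)
        rec = SpeciesRecord(
            species_id=sid,
            name=str(row["name"]),
            common_name=str(row.get("common_name", "")),
            min_depth=float(row["min_depth_m"]),
            max_depth=float(row["max_depth_m"]),
            prob_map=np.asarray(prob_maps[sid], dtype=float),
            suitability_threshold=suit,
        )
        rec.habitat3d = build_habitat3d(
            rec, grid, probability_threshold, src_lat_bounds, src_lon_bounds
        )
        records.append(rec)
    return SpeciesRegistry(records=records, predator_id=predator_id)
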