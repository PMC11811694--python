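"""Aerobic growth index: thresholds, viability volumes, and overlap.

The aerobic growth index (AGI) of species *i* is the ratio of environmental
oxygen supply to the species' temperature-dependent oxygen demand:

    AGI_i = pO2 / ( pO2_thr_i * (1/3)^(1-d) * exp( (j2-j1)/Tpref_i - (j2-j1)/T ) )

with T in Kelvin, j1 = 4500 K (anabolism activation energy over the Boltzmann
constant), j2 = 8000 K (catabolism), and d = 0.7 the metabolic scaling
coefficient.  At (Tpref, pO2_thr) the exponential vanishes and
AGI = 3^(1-d) = 3^0.3 exactly, for every species.

Species thresholds come from the monthly historical climatology inside the
species' 3-D habitat: Tpref is the volume-weighted median of in situ
temperature, pO2_thr the volume-weighted 10th percentile of pO2, and the
viability cutoff AGI_crit the volume-weighted 10th percentile of monthly
in-habitat AGI.  Viable habitat volume Omega sums the volume of habitat cells
with AGI strictly above AGI_crit; the predator-prey overlap Phi sums the
volume where both species' viable masks intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional

import numpy as np

from .grid import FieldSet, OceanGrid, RegionMasks

__all__ = [
    "KELVIN_OFFSET",
    "DEPTH_INTERVALS",
    "AGIParams",
    "SpeciesThresholds",
    "ViabilityResult",
    "OverlapValue",
    "weighted_percentile",
    "species_thresholds",
    "agi",
    "agi_crit",
    "viable_volume",
    "overlap_volume",
    "agi_rel",
]

KELVIN_OFFSET = 273.15

#: depth intervals (m) used for all stratified reporting
DEPTH_INTERVALS = ((0.0, 400.0), (400.0, 700.0), (700.0, 1000.0), (1000.0, 3500.0))


@dataclass(frozen=True)
class AGIParams:
    """Constants of the AGI demand term."""

    j1: float = 4500.0  # K
    j2: float = 8000.0  # K
    d: float = 0.7
    mass_ratio_base: float = 1.0 / 3.0

    def __post_init__(self):
        if not self.j2 > self.j1:
            raise ValueError("j2 must exceed j1")
        if not 0.0 < self.d < 1.0:
            raise ValueError("d must lie in (0, 1)")
        if not self.mass_ratio_base > 0:
            raise ValueError("mass_ratio_base must be positive")

    @property
    def demand_mass_factor(self) -> float:
        """(1/3)^(1-d); the supply/demand ratio at preferred conditions is its inverse."""
        return self.mass_ratio_base ** (1.0 - self.d)


@dataclass
class SpeciesThresholds:
    """Physiological thresholds of one species (Tpref C, pO2_thr mbar, AGI_crit)."""

    t_pref: float
    po2_thr: float
    agi_crit: Optional[float] = None

    def __post_init__(self):
        if not self.po2_thr > 0:
            raise ValueError("po2_thr must be positive")
        if self.agi_crit is not None and not self.agi_crit > 0:
            raise ValueError("agi_crit must be positive")


@dataclass
class ViabilityResult:
    """Per-species AGI field, viable mask and volume totals (km^3)."""

    agi_field: np.ndarray
    viable_mask: np.ndarray
    omega_total: float
    omega_by_level: np.ndarray
    omega_by_region: Dict[str, float] = dc_field(default_factory=dict)


@dataclass
class OverlapValue:
    """Predator-prey viable-habitat overlap Phi (km^3), total and stratified."""

    phi: float
    phi_pct_of_predator: float
    phi_by_interval: Dict[tuple, float]
    phi_shelf: float
    phi_by_region: Dict[str, float] = dc_field(default_factory=dict)


def weighted_percentile(values, weights, q: float) -> float:
    """Volume-weighted empirical-CDF percentile, lower-value rule.

    Returns the smallest value v such that the normalized cumulative weight of
    all samples <= v reaches q.  q=0 gives the minimum, q=1 the maximum; ties
    in ``values`` are aggregated before the rule is applied, so the result is
    independent of sample order.
    """
    values = np.asarray(values, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same length")
    if np.any(weights < 0):
        raise ValueError("negative weights")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all weights are zero")
    uniq, inv = np.unique(values, return_inverse=True)
    w = np.bincount(inv, weights=weights, minlength=uniq.size)
    cum = np.cumsum(w) / total
    idx = int(np.searchsorted(cum, q, side="left"))
    idx = min(idx, uniq.size - 1)
    return float(uniq[idx])


def _monthly_samples(field4d: np.ndarray, habitat3d: np.ndarray, grid: OceanGrid):
    """Flatten (month, cell) samples inside the habitat with volume weights."""
    hab = habitat3d & (grid.cell_volume > 0)
    if not hab.any():
        raise ValueError("empty habitat")
    nt = field4d.shape[0]
    vals = field4d[:, hab]  # (nt, ncell)
    w = np.broadcast_to(grid.cell_volume[hab], vals.shape)
    ok = np.isfinite(vals)
    return vals[ok], w[ok]


def species_thresholds(
    clim: FieldSet, habitat3d: np.ndarray, grid: OceanGrid
) -> SpeciesThresholds:
    """Tpref and pO2_thr from the monthly climatology inside the habitat.

    Tpref is the volume-weighted 50th percentile of in situ temperature,
    pO2_thr the volume-weighted 10th percentile of pO2; each climatological
    month contributes one sample per habitat cell, weighted by cell volume
    (months unweighted by length).
    """
    if clim.t_insitu is None or clim.po2 is None:
        raise ValueError("climatology lacks derived t_insitu/po2 fields")
    tv, tw = _monthly_samples(clim.t_insitu, habitat3d, grid)
    pv, pw = _monthly_samples(clim.po2, habitat3d, grid)
    return SpeciesThresholds(
        t_pref=weighted_percentile(tv, tw, 0.5),
        po2_thr=weighted_percentile(pv, pw, 0.1),
    )


def agi(t_insitu, po2, thresholds: SpeciesThresholds, params: AGIParams = AGIParams()):
    """AGI field from in situ temperature (C) and pO2 (mbar).

    Strictly increasing and linear in pO2, strictly decreasing in temperature
    (warming raises demand).  Temperatures are converted to Kelvin internally.
    """
    po2 = np.asarray(po2, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(po2 < 0):
            raise ValueError("negative pO2")
    t_k = np.asarray(t_insitu, dtype=float) + KELVIN_OFFSET
    tpref_k = thresholds.t_pref + KELVIN_OFFSET
    dj = params.j2 - params.j1
    demand = thresholds.po2_thr * params.demand_mass_factor * np.exp(dj / tpref_k - dj / t_k)
    return po2 / demand


def agi_crit(
    clim: FieldSet,
    habitat3d: np.ndarray,
    thresholds: SpeciesThresholds,
    grid: OceanGrid,
    params: AGIParams = AGIParams(),
) -> float:
    """Viability cutoff: volume-weighted 10th percentile of monthly in-habitat AGI."""
    if clim.t_insitu is None or clim.po2 is None:
        raise ValueError("climatology lacks derived t_insitu/po2 fields")
    agi4d = agi(clim.t_insitu, clim.po2, thresholds, params)
    av, aw = _monthly_samples(agi4d, habitat3d, grid)
    return weighted_percentile(av, aw, 0.1)


def viable_volume(
    agi_field: np.ndarray,
    agi_critical: float,
    habitat3d: np.ndarray,
    grid: OceanGrid,
    masks: Optional[RegionMasks] = None,
) -> ViabilityResult:
    """Viable habitat volume Omega: cells with AGI strictly above AGI_crit.

    ``agi_field`` is a 3-D (annual) field; boundary cells (AGI == AGI_crit)
    are excluded.
    """
    if agi_field.ndim == 4:
        agi_field = agi_field[0]
    with np.errstate(invalid="ignore"):
        viable = habitat3d & (agi_field > agi_critical)
    vol = np.where(viable, grid.cell_volume, 0.0)
    by_level = vol.sum(axis=(1, 2))
    by_region = {}
    if masks is not None:
        for name in ("shelf", "area48", "area58", "area88"):
            m2d = getattr(masks, name)
            by_region[name] = float(np.where(m2d[None, :, :], vol, 0.0).sum())
    return ViabilityResult(
        agi_field=agi_field,
        viable_mask=viable,
        omega_total=float(by_level.sum()),
        omega_by_level=by_level,
        omega_by_region=by_region,
    )


def _interval_slices(grid: OceanGrid):
    for zmin, zmax in DEPTH_INTERVALS:
        sel = (grid.depth_centers >= zmin) & (grid.depth_centers < zmax)
        yield (zmin, zmax), sel


def overlap_volume(
    pred: ViabilityResult,
    prey: ViabilityResult,
    grid: OceanGrid,
    masks: Optional[RegionMasks] = None,
) -> OverlapValue:
    """Overlap Phi: volume where predator and prey viable masks intersect."""
    both = pred.viable_mask & prey.viable_mask
    vol = np.where(both, grid.cell_volume, 0.0)
    phi = float(vol.sum())
    by_interval = {}
    for key, sel in _interval_slices(grid):
        by_interval[key] = float(vol[sel].sum())
    phi_shelf = 0.0
    by_region = {}
    if masks is not None:
        phi_shelf = float(np.where(masks.shelf[None, :, :], vol, 0.0).sum())
        for name in ("area48", "area58", "area88"):
            m2d = getattr(masks, name)
            by_region[name] = float(np.where(m2d[None, :, :], vol, 0.0).sum())
    pct = 100.0 * phi / pred.omega_total if pred.omega_total > 0 else float("nan")
    return OverlapValue(
        phi=phi,
        phi_pct_of_predator=pct,
        phi_by_interval=by_interval,
        phi_shelf=phi_shelf,
        phi_by_region=by_region,
    )


def agi_rel(agi_future: np.ndarray, agi_hist: np.ndarray) -> np.ndarray:
    """Relative AGI change in percent: 100 * (future/historical - 1).

    Species-independent: every species-specific factor of the AGI cancels in
    the ratio.  Cells with zero historical AGI return NaN.
    """
    agi_future = np.asarray(agi_future, dtype=float)
    agi_hist = np.asarray(agi_hist, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (agi_future / agi_hist - 1.0)
    return np.where(agi_hist == 0, np.nan, out)
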