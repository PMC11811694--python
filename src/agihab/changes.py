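"""Scenario analysis: drift correction, attribution, and change reports.

Given a historical monthly climatology, annual-mean future fields for one or
more emission scenarios, and a control run, this module produces the study's
result surfaces: in-habitat vertical profiles of temperature, pO2 and
relative AGI change; per-species viable-habitat (Omega) change; per-prey
overlap (Phi) change stratified by depth interval, shelf and region; and
prey-richness fields and profiles.

Species thresholds always come from the monthly historical climatology;
future (and like-for-like historical) viability is evaluated on annual-mean
in situ temperature and pO2.  Future temperature and oxygen concentration are
drift-corrected against the control run before pO2 is recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import seawater
from .agi import (
    DEPTH_INTERVALS,
    AGIParams,
    ViabilityResult,
    agi,
    agi_crit,
    agi_rel,
    overlap_volume,
    species_thresholds,
    viable_volume,
)
from .grid import FieldSet, OceanGrid, RegionMasks
from .habitat import SpeciesRegistry

__all__ = [
    "SCENARIOS",
    "FUTURE_PERIODS",
    "ScenarioSet",
    "ChangeReport",
    "drift_correct",
    "attribute_change",
    "habitat_profile",
    "omega_change_report",
    "phi_change_report",
    "prey_richness",
    "project_scenarios",
]

SCENARIOS = ("ssp126", "ssp245", "ssp370", "ssp585")
FUTURE_PERIODS = ("2091-2100", "2081-2100", "2098-2100")

_REGION_NAMES = ("shelf", "area48", "area58", "area88")


@dataclass
class ScenarioSet:
    """All field inputs of one projection run, on one grid."""

    historical: FieldSet  # monthly climatology, derived fields filled
    control_hist: FieldSet  # annual mean, historical period of the control run
    control_future: FieldSet  # annual mean, future period of the control run
    scenarios: Dict[str, FieldSet]  # annual-mean future fields per scenario
    future_period: str = "2091-2100"

    def __post_init__(self):
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenario labels: {sorted(unknown)}")
        if self.future_period not in FUTURE_PERIODS:
            raise ValueError(f"future_period must be one of {FUTURE_PERIODS}")


@dataclass
class ChangeReport:
    """Bundle of result tables and fields from one projection run."""

    profiles: pd.DataFrame
    omega_change: pd.DataFrame
    phi_change: pd.DataFrame
    richness_profiles: pd.DataFrame
    agi_rel_fields: Dict[str, np.ndarray] = field(default_factory=dict)
    richness_fields: Dict[str, np.ndarray] = field(default_factory=dict)
    thresholds: pd.DataFrame = field(default_factory=pd.DataFrame)
    viability_hist: Dict[int, ViabilityResult] = field(default_factory=dict)
    viability_future: Dict[str, Dict[int, ViabilityResult]] = field(default_factory=dict)


def drift_correct(scenario_future, control_future, control_hist):
    """Remove model drift: X - (X_control,future - X_control,hist).

    Linear in its first argument; a zero-drift control leaves the field
    untouched, and correcting the control's own future returns control_hist.
    """
    scenario_future = np.asarray(scenario_future, dtype=float)
    control_future = np.asarray(control_future, dtype=float)
    control_hist = np.asarray(control_hist, dtype=float)
    if scenario_future.shape != control_future.shape or control_future.shape != control_hist.shape:
        raise ValueError("drift correction requires identically shaped fields")
    return scenario_future - (control_future - control_hist)


def _recompute_po2(o2_conc, t_insitu, sp, grid: OceanGrid):
    depth = grid.depth_centers[None, :, None, None]
    lat = grid.lat_centers[None, None, :, None]
    rho = seawater.insitu_density(t_insitu, sp, depth, lat)
    molal = seawater.o2_molal_from_volumetric(o2_conc, rho)
    molal = np.where(np.isnan(molal), np.nan, np.maximum(molal, 0.0))
    return seawater.compute_po2(molal, t_insitu, sp)


def attribute_change(
    hist: FieldSet, future: FieldSet, mode: str, grid: OceanGrid
) -> tuple[np.ndarray, np.ndarray]:
    """(T, pO2) pair isolating one driver of AGI change.

    ``temperature_only`` pairs future temperature with historical pO2;
    ``oxygen_only`` keeps historical temperature and recomputes pO2 from the
    future oxygen concentration with historical temperature and salinity;
    ``both`` is the full signal.  ``hist`` and ``future`` must be annual-mean
    field sets with derived fields filled.
    """
    if mode == "temperature_only":
        return future.t_insitu, hist.po2
    if mode == "oxygen_only":
        po2 = _recompute_po2(future.o2_conc, hist.t_insitu, hist.sp, grid)
        return hist.t_insitu, po2
    if mode == "both":
        return future.t_insitu, future.po2
    raise ValueError(f"unknown attribution mode '{mode}'")


def habitat_profile(field3d: np.ndarray, habitat3d: np.ndarray, grid: OceanGrid) -> np.ndarray:
    """Volume-weighted in-habitat mean per depth level (NaN where habitat is empty)."""
    if field3d.ndim == 4:
        field3d = field3d[0]
    w = np.where(habitat3d & np.isfinite(field3d), grid.cell_volume, 0.0)
    num = np.nansum(np.where(w > 0, field3d, 0.0) * w, axis=(1, 2))
    den = w.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = num / den
    return np.where(den > 0, prof, np.nan)


def _pct_change(future: float, hist: float) -> float:
    """Percent change with the historical value as denominator; NaN if undefined."""
    if hist == 0 or not np.isfinite(hist):
        return float("nan")
    return 100.0 * (future - hist) / hist


def omega_change_report(
    registry: SpeciesRegistry,
    hist_viability: Dict[int, ViabilityResult],
    future_viability: Dict[int, ViabilityResult],
    grid: OceanGrid,
    scenario: str = "",
) -> pd.DataFrame:
    """Per-species viable-habitat change: total and per depth interval, in %.

    The whole-habitat number 100*(Omega_f - Omega_h)/Omega_h is the
    vertically averaged change.
    """
    rows = []
    for rec in registry:
        h = hist_viability[rec.species_id]
        f = future_viability[rec.species_id]
        row = {
            "scenario": scenario,
            "species_id": rec.species_id,
            "name": rec.name,
            "omega_hist_km3": h.omega_total,
            "omega_future_km3": f.omega_total,
            "omega_change_pct": _pct_change(f.omega_total, h.omega_total),
        }
        for (zmin, zmax) in DEPTH_INTERVALS:
            sel = (grid.depth_centers >= zmin) & (grid.depth_centers < zmax)
            oh = float(h.omega_by_level[sel].sum())
            of = float(f.omega_by_level[sel].sum())
            row[f"omega_change_pct_{int(zmin)}_{int(zmax)}m"] = _pct_change(of, oh)
        rows.append(row)
    return pd.DataFrame(rows)


def phi_change_report(
    registry: SpeciesRegistry,
    hist_viability: Dict[int, ViabilityResult],
    future_viability: Dict[int, ViabilityResult],
    grid: OceanGrid,
    masks: RegionMasks,
    scenario: str = "",
) -> pd.DataFrame:
    """Per-prey overlap change with the predator: whole habitat, shelf, intervals, regions."""
    pid = registry.predator_id
    rows = []
    for rec in registry.prey:
        oh = overlap_volume(hist_viability[pid], hist_viability[rec.species_id], grid, masks)
        of = overlap_volume(future_viability[pid], future_viability[rec.species_id], grid, masks)
        row = {
            "scenario": scenario,
            "species_id": rec.species_id,
            "name": rec.name,
            "phi_hist_km3": oh.phi,
            "phi_future_km3": of.phi,
            "phi_hist_pct_of_predator": oh.phi_pct_of_predator,
            "phi_change_pct": _pct_change(of.phi, oh.phi),
            "phi_shelf_hist_km3": oh.phi_shelf,
            "phi_shelf_change_pct": _pct_change(of.phi_shelf, oh.phi_shelf),
        }
        for (zmin, zmax) in DEPTH_INTERVALS:
            key = (zmin, zmax)
            row[f"phi_hist_km3_{int(zmin)}_{int(zmax)}m"] = oh.phi_by_interval[key]
            row[f"phi_change_pct_{int(zmin)}_{int(zmax)}m"] = _pct_change(
                of.phi_by_interval[key], oh.phi_by_interval[key]
            )
        for region in ("area48", "area58", "area88"):
            row[f"phi_change_pct_{region}"] = _pct_change(
                of.phi_by_region.get(region, 0.0), oh.phi_by_region.get(region, 0.0)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def prey_richness(
    registry: SpeciesRegistry,
    viability_by_species: Dict[int, ViabilityResult],
    masks: RegionMasks,
    grid: OceanGrid,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Prey counts in the predator's viable habitat.

    Returns the 3-D richness field (NaN outside the predator's viable mask),
    area-weighted average profiles per region, and the top-1000 m
    column-mean richness map.
    """
    pred = viability_by_species[registry.predator_id]
    counts = np.zeros(grid.shape, dtype=float)
    for rec in registry.prey:
        counts += viability_by_species[rec.species_id].viable_mask
    rich = np.where(pred.viable_mask, counts, np.nan)

    regions = {
        "all": masks.domain,
        "area48": masks.area48,
        "area58": masks.area58,
        "area88": masks.area88,
    }
    rows = []
    area = grid.cell_area[None, :, :]
    for name, m2d in regions.items():
        w = np.where(pred.viable_mask & m2d[None, :, :], area, 0.0)
        num = np.nansum(np.where(w > 0, rich, 0.0) * w, axis=(1, 2))
        den = w.sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            prof = np.where(den > 0, num / den, np.nan)
        for z, v in zip(grid.depth_centers, prof):
            rows.append({"region": name, "depth_level_m": z, "mean_prey_count": v})
    profiles = pd.DataFrame(rows)

    top = grid.depth_centers <= 1000.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_map = np.nanmean(np.where(top[:, None, None], rich, np.nan), axis=0)
    return rich, profiles, col_map


def _derive_annual(fields: FieldSet, grid: OceanGrid) -> FieldSet:
    out = fields.copy()
    if out.t_insitu is None or out.po2 is None:
        seawater.add_derived_fields(out, grid)
    return out


def project_scenarios(
    scenario_set: ScenarioSet,
    registry: SpeciesRegistry,
    grid: OceanGrid,
    masks: RegionMasks,
    params: AGIParams = AGIParams(),
    scenarios: Optional[List[str]] = None,
    drift_correction: bool = True,
) -> ChangeReport:
    """Run the full change analysis for the requested scenarios.

    Thresholds (Tpref, pO2_thr, AGI_crit) per species from the monthly
    historical climatology; historical baseline viability from the annual
    mean of the derived historical fields; future viability from
    drift-corrected annual future fields.
    """
    clim = scenario_set.historical
    if clim.n_time != 12:
        raise ValueError("historical climatology must have 12 months")
    if clim.t_insitu is None or clim.po2 is None:
        seawater.add_derived_fields(clim, grid)
    requested = list(scenarios or scenario_set.scenarios.keys())
    missing = [s for s in requested if s not in scenario_set.scenarios]
    if missing:
        raise ValueError(f"no fields for requested scenarios: {missing}")

    thr_rows = []
    hist_viab: Dict[int, ViabilityResult] = {}
    hist_annual = clim.annual_mean()
    for rec in registry:
        thr = species_thresholds(clim, rec.habitat3d, grid)
        thr.agi_crit = agi_crit(clim, rec.habitat3d, thr, grid, params)
        rec.thresholds = thr
        thr_rows.append(
            {
                "species_id": rec.species_id,
                "name": rec.name,
                "t_pref_c": thr.t_pref,
                "po2_thr_mbar": thr.po2_thr,
                "agi_crit": thr.agi_crit,
            }
        )
        agi_h = agi(hist_annual.t_insitu[0], hist_annual.po2[0], thr, params)
        hist_viab[rec.species_id] = viable_volume(agi_h, thr.agi_crit, rec.habitat3d, grid, masks)
    thresholds = pd.DataFrame(thr_rows)

    ctrl_h = _derive_annual(scenario_set.control_hist, grid)
    ctrl_f = _derive_annual(scenario_set.control_future, grid)

    profile_rows = []
    omega_tables, phi_tables, richness_tables = [], [], []
    agi_rel_fields: Dict[str, np.ndarray] = {}
    richness_fields: Dict[str, np.ndarray] = {}
    future_viab_all: Dict[str, Dict[int, ViabilityResult]] = {}

    pred_hab = registry.predator.habitat3d

    rich_h, richprof_h, colmap_h = prey_richness(registry, hist_viab, masks, grid)
    richprof_h["scenario"] = "historical"
    richness_tables.append(richprof_h)
    richness_fields["historical"] = rich_h
    richness_fields["historical_top1000m"] = colmap_h

    for name in requested:
        fut = _derive_annual(scenario_set.scenarios[name], grid)
        if drift_correction:
            t_corr = drift_correct(fut.t_insitu, ctrl_f.t_insitu, ctrl_h.t_insitu)
            o2_corr = drift_correct(fut.o2_conc, ctrl_f.o2_conc, ctrl_h.o2_conc)
        else:
            t_corr, o2_corr = fut.t_insitu, fut.o2_conc
        po2_corr = _recompute_po2(o2_corr, t_corr, fut.sp, grid)
        corrected = FieldSet(
            period_label=scenario_set.future_period,
            scenario_label=name,
            theta=fut.theta,
            sp=fut.sp,
            o2_conc=o2_corr,
            t_insitu=t_corr,
            po2=po2_corr,
        )

        # species-independent AGI ratio (any thresholds give the same AGIrel)
        ref_thr = registry.predator.thresholds
        agi_h3 = agi(hist_annual.t_insitu[0], hist_annual.po2[0], ref_thr, params)
        agi_f3 = agi(corrected.t_insitu[0], corrected.po2[0], ref_thr, params)
        rel = agi_rel(agi_f3, agi_h3)
        agi_rel_fields[name] = rel

        d_t = corrected.t_insitu[0] - hist_annual.t_insitu[0]
        d_po2 = corrected.po2[0] - hist_annual.po2[0]
        for z, a, b, c in zip(
            grid.depth_centers,
            habitat_profile(d_t, pred_hab, grid),
            habitat_profile(d_po2, pred_hab, grid),
            habitat_profile(rel, pred_hab, grid),
        ):
            profile_rows.append(
                {
                    "scenario": name,
                    "depth_level_m": z,
                    "delta_t_c": a,
                    "delta_po2_mbar": b,
                    "agi_rel_pct": c,
                }
            )

        fut_viab: Dict[int, ViabilityResult] = {}
        for rec in registry:
            agi_f = agi(corrected.t_insitu[0], corrected.po2[0], rec.thresholds, params)
            fut_viab[rec.species_id] = viable_volume(
                agi_f, rec.thresholds.agi_crit, rec.habitat3d, grid, masks
            )
        future_viab_all[name] = fut_viab

        omega_tables.append(omega_change_report(registry, hist_viab, fut_viab, grid, name))
        phi_tables.append(phi_change_report(registry, hist_viab, fut_viab, grid, masks, name))
        rich_f, richprof_f, colmap_f = prey_richness(registry, fut_viab, masks, grid)
        richprof_f["scenario"] = name
        richness_tables.append(richprof_f)
        richness_fields[name] = rich_f
        richness_fields[f"{name}_top1000m"] = colmap_f

    return ChangeReport(
        profiles=pd.DataFrame(profile_rows),
        omega_change=pd.concat(omega_tables, ignore_index=True) if omega_tables else pd.DataFrame(),
        phi_change=pd.concat(phi_tables, ignore_index=True) if phi_tables else pd.DataFrame(),
        richness_profiles=pd.concat(richness_tables, ignore_index=True),
        agi_rel_fields=agi_rel_fields,
        richness_fields=richness_fields,
        thresholds=thresholds,
        viability_hist=hist_viab,
        viability_future=future_viab_all,
    )
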