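"""Synthetic Southern Ocean inputs: grid, climatology, scenarios, species.

Generates seeded, fully deterministic stand-ins for the ocean-model output
and species distribution maps the analysis consumes, with the statistical
structure the method assumes: a cold fresh surface layer with a seasonal
cycle confined to the upper ocean, a warm oxygen-poor subsurface water mass
(Circumpolar Deep Water analogue) near 500 m, oxygen decreasing from the
surface to a mid-depth minimum, a shallow coastal shelf band south of a deep
basin, and quasi-circumpolar species bands with distinct depth ranges.

Scenario forcing is an analytic perturbation scaled per scenario:
surface-intensified warming (default 1.2 C at the surface, a ~0.3 C
subsurface maximum near 600 m) and an oxygen redistribution with gains in
the upper ocean and losses peaking near 600 m, plus a slow uniform control
drift carried by all future fields.  Default scenario scales 0.25 / 0.5 /
0.75 / 1.0 give a monotone forcing ladder, not a claim about real scenario
spacing.

All randomness flows from one named generator seeded by ``SynthConfig.seed``;
noise is purely spatial (identical across months), so a zero-seasonality
configuration has bit-identical months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .changes import ScenarioSet
from .grid import FieldSet, OceanGrid, make_ocean_grid
from .habitat import SpeciesRecord, SpeciesRegistry, extrude_depth, threshold_probability, threshold_suitability

__all__ = ["SynthConfig", "make_grid", "make_climatology", "make_scenarios", "make_species_set", "generate_all"]

DEFAULT_SCENARIO_SCALES = {"ssp126": 0.25, "ssp245": 0.5, "ssp370": 0.75, "ssp585": 1.0}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic generator; defaults mirror the study conditions."""

    seed: int
    n_lon: int = 90
    n_lat: int = 17
    n_depth: int = 20
    lat_range: Tuple[float, float] = (-78.0, -45.0)
    depth_max: float = 3500.0
    # climatology shape
    seasonal_amp_t: float = 1.0  # C, surface seasonal amplitude
    t_surface_south: float = -1.8  # C at the southern boundary
    t_surface_north: float = 4.0  # C at 45 S
    t_deep: float = -0.5  # C abyssal background
    cdw_amp: float = 1.5  # C subsurface (CDW-like) warm anomaly
    cdw_depth: float = 500.0  # m
    o2_surface: float = 340.0  # mmol m-3 southern surface value
    o2_deep: float = 240.0  # mmol m-3 background
    o2_min_amp: float = 35.0  # mmol m-3 mid-depth minimum amplitude
    o2_min_depth: float = 600.0  # m
    # scenario forcing (full scale)
    warming_surface: float = 1.2  # C
    warming_subsurface: float = 0.3  # C, peak near deox depth
    warming_decay: float = 250.0  # m e-folding of surface warming
    o2_gain_surface: float = 12.0  # mmol m-3 upper-ocean gain
    deox_peak: float = 20.0  # mmol m-3 loss at peak depth
    deox_peak_depth: float = 600.0  # m
    deox_width: float = 180.0  # m
    drift_t: float = 0.05  # C control drift over the run
    drift_o2: float = -2.0  # mmol m-3
    scenario_scales: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_SCALES)
    )
    # noise (spatial, shared by all months)
    noise_sd_t: float = 0.05
    noise_sd_s: float = 0.01
    noise_sd_o2: float = 2.0

    def __post_init__(self):
        if self.n_lon < 2 or self.n_lat < 2 or self.n_depth < 2:
            raise ValueError("grid sizes must be at least 2")
        for k, v in self.scenario_scales.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"scenario scale {k}={v} outside [0, 1]")

    def zero_seasonality(self) -> "SynthConfig":
        return replace(self, seasonal_amp_t=0.0)


def make_grid(config: SynthConfig) -> OceanGrid:
    """Regular lon-lat grid, depth levels thickening with depth, shelf + basin bathymetry.

    The southernmost rows form a 500 m continental shelf band; bathymetry
    ramps down a slope to a ~3300 m basin with gentle zonal relief.
    """
    lon_bounds = np.linspace(-180.0, 180.0, config.n_lon + 1)
    lat_bounds = np.linspace(config.lat_range[0], config.lat_range[1], config.n_lat + 1)
    stretch = 2.2
    frac = (np.exp(stretch * np.linspace(0, 1, config.n_depth + 1)) - 1.0) / (
        np.exp(stretch) - 1.0
    )
    depth_bounds = config.depth_max * frac

    lat_c = 0.5 * (lat_bounds[:-1] + lat_bounds[1:])
    lon_c = 0.5 * (lon_bounds[:-1] + lon_bounds[1:])
    shelf_lat, slope_lat = -72.0, -67.0
    basin = 3300.0 + 100.0 * np.sin(2.0 * np.deg2rad(lon_c))[None, :]
    ramp = np.clip((lat_c - shelf_lat) / (slope_lat - shelf_lat), 0.0, 1.0)[:, None]
    bathy = 500.0 + ramp * (basin - 500.0)
    return make_ocean_grid(lon_bounds, lat_bounds, depth_bounds, bathy)


def _profiles(config: SynthConfig, grid: OceanGrid):
    z = grid.depth_centers[:, None, None]
    lat = grid.lat_centers[None, :, None]
    lat_frac = (lat - config.lat_range[0]) / (config.lat_range[1] - config.lat_range[0])
    t_surf = config.t_surface_south + lat_frac * (config.t_surface_north - config.t_surface_south)
    theta = (
        config.t_deep
        + (t_surf - config.t_deep) * np.exp(-z / 120.0)
        + config.cdw_amp * np.exp(-(((z - config.cdw_depth) / 350.0) ** 2))
    )
    sal = 34.7 - 0.8 * np.exp(-z / 150.0) + 0.05 * lat_frac
    o2_surf_anom = (config.o2_surface - config.o2_deep) - 30.0 * lat_frac
    o2 = (
        config.o2_deep
        + o2_surf_anom * np.exp(-z / 180.0)
        - config.o2_min_amp * np.exp(-(((z - config.o2_min_depth) / 400.0) ** 2))
    )
    return theta, sal, o2


def make_climatology(grid: OceanGrid, config: SynthConfig) -> FieldSet:
    """Monthly (12-step) climatological potential T, salinity and O2 concentration.

    Seasonal cycle on temperature only, confined to the upper ~200 m; seeded
    spatial noise shared by all months; land/below-floor cells are NaN.
    """
    rng = np.random.default_rng(config.seed)
    theta0, sal0, o20 = _profiles(config, grid)
    nz, ny, nx = grid.shape
    noise_t = rng.normal(0.0, config.noise_sd_t, (nz, ny, nx))
    noise_s = rng.normal(0.0, config.noise_sd_s, (nz, ny, nx))
    noise_o2 = rng.normal(0.0, config.noise_sd_o2, (nz, ny, nx))

    z = grid.depth_centers[:, None, None]
    months = np.arange(12)
    seasonal = config.seasonal_amp_t * np.cos(2.0 * np.pi * (months[:, None, None, None] - 1) / 12.0)
    seasonal = seasonal * np.exp(-((z[None] / 120.0) ** 2))

    theta = theta0[None] + seasonal + noise_t[None]
    sal = np.broadcast_to(sal0 + noise_s, (12, nz, ny, nx)).copy()
    o2 = np.broadcast_to(np.maximum(o20 + noise_o2, 1.0), (12, nz, ny, nx)).copy()

    dry = ~grid.wet_mask
    for a in (theta, sal, o2):
        a[:, dry] = np.nan
    return FieldSet(
        period_label="1995-2014", scenario_label="historical", theta=theta, sp=sal, o2_conc=o2
    )


def _forcing(config: SynthConfig, grid: OceanGrid):
    """Full-scale (scale=1) analytic perturbation profiles dT(z), dO2(z)."""
    z = grid.depth_centers[:, None, None]
    d_t = config.warming_surface * np.exp(-z / config.warming_decay) + (
        config.warming_subsurface
        * np.exp(-(((z - config.deox_peak_depth) / 350.0) ** 2))
    )
    d_o2 = config.o2_gain_surface * np.exp(-((z / 300.0) ** 2)) - config.deox_peak * np.exp(
        -(((z - config.deox_peak_depth) / config.deox_width) ** 2)
    )
    return d_t, d_o2


def make_scenarios(
    clim: FieldSet, grid: OceanGrid, config: SynthConfig, future_period: str = "2091-2100"
) -> ScenarioSet:
    """Annual future fields per scenario plus a drifting control run.

    future = historical annual mean + scale * (dT, dO2) + drift;
    control_future carries the drift only, so drift correction recovers the
    pure forced signal.
    """
    hist_annual = clim.annual_mean()
    d_t, d_o2 = _forcing(config, grid)

    def perturbed(scale: float, with_drift: bool, label: str) -> FieldSet:
        theta = hist_annual.theta.copy()
        o2 = hist_annual.o2_conc.copy()
        theta = theta + scale * d_t[None]
        o2 = o2 + scale * d_o2[None]
        if with_drift:
            theta = theta + config.drift_t
            o2 = o2 + config.drift_o2
        return FieldSet(
            period_label=future_period,
            scenario_label=label,
            theta=theta,
            sp=hist_annual.sp.copy(),
            o2_conc=np.where(np.isnan(o2), np.nan, np.maximum(o2, 1.0)),
        )

    scenarios = {
        name: perturbed(scale, True, name) for name, scale in config.scenario_scales.items()
    }
    return ScenarioSet(
        historical=clim,
        control_hist=perturbed(0.0, False, "control"),
        control_future=perturbed(0.0, True, "control"),
        scenarios=scenarios,
        future_period=future_period,
    )


def _band(coord: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth 0-1 bump over [lo, hi]: ~0.95 plateau in the core, tapered edges."""
    frac = (coord - lo) / (hi - lo)
    tri = np.clip(2.0 * np.minimum(frac, 1.0 - frac), 0.0, 1.0)
    return 0.95 * tri**0.3


_SPECIES_SPECS = [
    # (id, name, common, zmin, zmax, lat band, lon sector or None, suitability thr)
    (1, "Pseudodissostichus major", "synthetic predator", 0, 2210, (-78.0, -45.2), None, None),
    (2, "Pagothenioides littoralis", "shallow-shelf prey", 0, 30, (-78.0, -71.0), None, None),
    (3, "Notothenioides shelfi", "mid-shelf prey", 0, 1000, (-78.0, -70.0), None, None),
    (4, "Mesopelagicus circumpolaris", "subsurface open-ocean prey", 200, 800, (-72.0, -48.0), None, None),
    (5, "Bathydraco profundus", "deep prey", 500, 2000, (-75.0, -50.0), None, None),
    (6, "Sectorius orientalis", "sector-restricted prey", 100, 600, (-74.0, -55.0), (0.0, 120.0), None),
    (7, "Euphausioides australis", "krill-like prey", 0, 600, (-76.0, -50.0), None, None),
    (8, "Teuthis synthetica", "squid-like prey", 200, 2500, (-75.0, -48.0), None, 0.228),
]


def make_species_set(
    grid: OceanGrid, config: SynthConfig, probability_threshold: float = 0.0
) -> SpeciesRegistry:
    """One domain-spanning predator plus seven prey archetypes with 3-D habitats.

    Archetypes cover shallow-shelf, mid-shelf, subsurface open-ocean, deep,
    sector-restricted, krill-like and squid-like (suitability-thresholded)
    distributions; every prey's lateral footprint lies inside the predator's.
    """
    lat = grid.lat_centers
    lon = grid.lon_centers
    records = []
    for sid, name, common, zmin, zmax, lat_band, lon_sector, suit_thr in _SPECIES_SPECS:
        p = np.repeat(_band(lat, *lat_band)[:, None], lon.size, axis=1)
        if lon_sector is not None:
            in_sector = (lon >= lon_sector[0]) & (lon < lon_sector[1])
            p = p * in_sector[None, :]
        if suit_thr is not None:
            p = 0.6 * p / 0.95  # suitability scale, core ~0.6 >> threshold
        rec = SpeciesRecord(
            species_id=sid,
            name=name,
            common_name=common,
            min_depth=float(zmin),
            max_depth=float(zmax),
            prob_map=p,
            suitability_threshold=suit_thr,
        )
        if rec.is_squid:
            mask2d = threshold_suitability(rec.prob_map, rec.suitability_threshold)
        else:
            mask2d = threshold_probability(rec.prob_map, probability_threshold)
        rec.habitat3d = extrude_depth(mask2d, rec.min_depth, rec.max_depth, grid)
        records.append(rec)
    return SpeciesRegistry(records=records, predator_id=1)


def generate_all(
    config: SynthConfig, probability_threshold: float = 0.0, future_period: str = "2091-2100"
):
    """Grid, monthly climatology, scenario set and species registry in one call."""
    grid = make_grid(config)
    clim = make_climatology(grid, config)
    scen = make_scenarios(clim, grid, config, future_period)
    registry = make_species_set(grid, config, probability_threshold)
    return grid, clim, scen, registry
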