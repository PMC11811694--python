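"""Shared fixtures: one full synthetic run, reused across the suite."""

import numpy as np
import pytest

from agihab import (
    SynthConfig,
    ccamlr_masks,
    generate_all,
    make_ocean_grid,
    project_scenarios,
)
from agihab import seawater

SEED = 1234


@pytest.fixture(scope="session")
def config():
    return SynthConfig(seed=SEED)


@pytest.fixture(scope="session")
def bundle(config):
    """(grid, clim, scenario_set, registry, masks) with derived fields filled."""
    grid, clim, scen, registry = generate_all(config)
    seawater.add_derived_fields(clim, grid)
    masks = ccamlr_masks(grid)
    return grid, clim, scen, registry, masks


@pytest.fixture(scope="session")
def report(bundle):
    grid, clim, scen, registry, masks = bundle
    return project_scenarios(scen, registry, grid, masks)


@pytest.fixture(scope="session")
def flat_bundle(config):
    """Zero-seasonality twin of the default run (months bit-identical)."""
    cfg = config.zero_seasonality()
    grid, clim, scen, registry = generate_all(cfg)
    seawater.add_derived_fields(clim, grid)
    return grid, clim, scen, registry


def toy_grid(bathy, depth_bounds=(0.0, 100.0, 300.0, 700.0, 1200.0), lat0=-70.0, dlat=1.0):
    """Small grid helper: one column per bathymetry entry unless 2-D given."""
    bathy = np.atleast_2d(np.asarray(bathy, dtype=float))
    ny, nx = bathy.shape
    lat_bounds = lat0 + dlat * np.arange(ny + 1)
    lon_bounds = np.linspace(-180.0, -180.0 + 2.0 * nx, nx + 1)
    return make_ocean_grid(lon_bounds, lat_bounds, np.asarray(depth_bounds, float), bathy)


@pytest.fixture
def grid_factory():
    return toy_grid
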