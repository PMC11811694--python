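"""Grid geometry, region masks, and CF-style NetCDF I/O.

The analysis lives on a regular lon-lat-depth grid.  ``OceanGrid`` carries the
coordinate bounds, per-cell areas, bathymetry and wet cell volumes; every mask
and field in the package is an array on this grid.  Volumes use partial bottom
cells: the wet thickness of a layer is clipped to the local bathymetry, so the
discrete ocean volume matches the bathymetric volume closely.

Conventions: depth is metres positive down, longitudes in [-180, 180),
latitudes in degrees north (negative in the study domain), missing values are
NaN (never zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

__all__ = [
    "EARTH_RADIUS_KM",
    "DOMAIN_LAT_MAX",
    "DOMAIN_DEPTH_MAX",
    "SHELF_ISOBATH_M",
    "OceanGrid",
    "FieldSet",
    "RegionMasks",
    "make_ocean_grid",
    "clip_domain",
    "shelf_mask",
    "ccamlr_masks",
    "load_fields",
    "write_fields",
    "write_mask",
    "load_mask",
    "region_volume_table",
]

EARTH_RADIUS_KM = 6371.0
#: analysis domain boundary: strictly south of 45 S
DOMAIN_LAT_MAX = -45.0
#: deepest level centre retained (m)
DOMAIN_DEPTH_MAX = 3185.0
#: isobath defining the Antarctic continental shelf (m)
SHELF_ISOBATH_M = 1000.0

#: CCAMLR Convention Area longitude sectors, degrees east
CCAMLR_BOUNDS = {"area48": (-70.0, 30.0), "area58": (30.0, 150.0)}


@dataclass
class OceanGrid:
    """Regular lon/lat/depth geometry with wet cell volumes.

    Attributes
    ----------
    lon_centers, lat_centers : 1-D arrays, degrees
    lon_bounds, lat_bounds : 1-D arrays of length n+1, degrees
    depth_centers : 1-D array, m positive down
    depth_bounds : 1-D array of length nz+1, m
    cell_area : (nlat, nlon) array, km^2
    bathymetry : (nlat, nlon) array, m (0 marks land)
    cell_volume : (nz, nlat, nlon) array, km^3 (0 below the seafloor)
    """

    lon_centers: np.ndarray
    lat_centers: np.ndarray
    lon_bounds: np.ndarray
    lat_bounds: np.ndarray
    depth_centers: np.ndarray
    depth_bounds: np.ndarray
    cell_area: np.ndarray
    bathymetry: np.ndarray
    cell_volume: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("lon_centers", "lat_centers", "depth_centers"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.size > 1 and not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
                raise ValueError(f"{name} must be strictly monotone")
        self.lon_bounds = np.asarray(self.lon_bounds, dtype=float)
        self.lat_bounds = np.asarray(self.lat_bounds, dtype=float)
        self.depth_bounds = np.asarray(self.depth_bounds, dtype=float)
        self.cell_area = np.asarray(self.cell_area, dtype=float)
        self.bathymetry = np.asarray(self.bathymetry, dtype=float)
        if np.any(np.diff(self.depth_bounds) <= 0):
            raise ValueError("depth_bounds must be increasing (contiguous layers)")
        if self.cell_volume is None:
            self.cell_volume = self._wet_volumes()
        else:
            self.cell_volume = np.asarray(self.cell_volume, dtype=float)

    def _wet_volumes(self) -> np.ndarray:
        """Partial-cell volumes: area times wet thickness clipped to bathymetry."""
        top = self.depth_bounds[:-1][:, None, None]
        bot = self.depth_bounds[1:][:, None, None]
        bathy = self.bathymetry[None, :, :]
        wet_thickness = np.clip(np.minimum(bot, bathy) - top, 0.0, None)
        return self.cell_area[None, :, :] * wet_thickness * 1e-3  # m -> km

    @property
    def shape(self) -> tuple:
        return (self.depth_centers.size, self.lat_centers.size, self.lon_centers.size)

    @property
    def wet_mask(self) -> np.ndarray:
        """Boolean (nz, nlat, nlon): cell centre above the seafloor."""
        return self.depth_centers[:, None, None] < self.bathymetry[None, :, :]

    @property
    def total_volume(self) -> float:
        return float(self.cell_volume.sum())

    def level_index(self, depth_m: float) -> int:
        return int(np.argmin(np.abs(self.depth_centers - depth_m)))


@dataclass
class FieldSet:
    """Gridded hydrographic fields for one period/scenario.

    Arrays have shape (ntime, nz, nlat, nlon) with ntime 12 (monthly
    climatology) or 1 (annual mean).  ``theta`` is potential temperature (C),
    ``sp`` practical salinity, ``o2_conc`` oxygen concentration (mmol m-3);
    ``t_insitu`` (C) and ``po2`` (mbar) are derived on demand.
    """

    period_label: str
    scenario_label: str
    theta: np.ndarray
    sp: np.ndarray
    o2_conc: np.ndarray
    t_insitu: Optional[np.ndarray] = None
    po2: Optional[np.ndarray] = None

    @property
    def n_time(self) -> int:
        return self.theta.shape[0]

    def annual_mean(self) -> "FieldSet":
        """Time-mean of every present field, as a 1-time FieldSet."""

        def mean(a):
            if a is None:
                return None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                return np.nanmean(a, axis=0, keepdims=True)

        return FieldSet(
            period_label=self.period_label,
            scenario_label=self.scenario_label,
            theta=mean(self.theta),
            sp=mean(self.sp),
            o2_conc=mean(self.o2_conc),
            t_insitu=mean(self.t_insitu),
            po2=mean(self.po2),
        )

    def copy(self) -> "FieldSet":
        cp = lambda a: None if a is None else a.copy()
        return FieldSet(
            self.period_label,
            self.scenario_label,
            cp(self.theta),
            cp(self.sp),
            cp(self.o2_conc),
            cp(self.t_insitu),
            cp(self.po2),
        )


@dataclass
class RegionMasks:
    """2-D boolean masks partitioning the analysis domain."""

    domain: np.ndarray
    shelf: np.ndarray
    area48: np.ndarray
    area58: np.ndarray
    area88: np.ndarray

    def __post_init__(self):
        for a, b in (("area48", "area58"), ("area48", "area88"), ("area58", "area88")):
            if np.any(getattr(self, a) & getattr(self, b)):
                raise ValueError(f"{a} and {b} overlap")
        if np.any(self.shelf & ~self.domain):
            raise ValueError("shelf mask extends outside the domain")


def make_ocean_grid(lon_bounds, lat_bounds, depth_bounds, bathymetry) -> OceanGrid:
    """Build an OceanGrid from coordinate bounds and bathymetry.

    Cell areas use the exact spherical-zone formula
    A = R^2 * dlambda * (sin(phi2) - sin(phi1)).
    """
    lon_bounds = np.asarray(lon_bounds, dtype=float)
    lat_bounds = np.asarray(lat_bounds, dtype=float)
    depth_bounds = np.asarray(depth_bounds, dtype=float)
    lon_c = 0.5 * (lon_bounds[:-1] + lon_bounds[1:])
    lat_c = 0.5 * (lat_bounds[:-1] + lat_bounds[1:])
    depth_c = 0.5 * (depth_bounds[:-1] + depth_bounds[1:])
    dlam = np.deg2rad(np.diff(lon_bounds))
    sinphi = np.sin(np.deg2rad(lat_bounds))
    band = EARTH_RADIUS_KM**2 * np.diff(sinphi)
    area = band[:, None] * dlam[None, :]
    return OceanGrid(
        lon_centers=lon_c,
        lat_centers=lat_c,
        lon_bounds=lon_bounds,
        lat_bounds=lat_bounds,
        depth_centers=depth_c,
        depth_bounds=depth_bounds,
        cell_area=area,
        bathymetry=np.asarray(bathymetry, dtype=float),
    )


def clip_domain(fields: FieldSet, grid: OceanGrid) -> tuple[FieldSet, OceanGrid]:
    """Restrict fields and grid to lat < -45 and depth centres <= 3185 m.

    Idempotent; returns new objects sharing no arrays with the inputs.
    """
    keep_lat = grid.lat_centers < DOMAIN_LAT_MAX
    keep_z = grid.depth_centers <= DOMAIN_DEPTH_MAX
    iz = np.flatnonzero(keep_z)
    iy = np.flatnonzero(keep_lat)
    if iz.size == 0 or iy.size == 0:
        raise ValueError("clip_domain would leave an empty grid")

    lat_bounds = np.concatenate([grid.lat_bounds[iy], [grid.lat_bounds[iy[-1] + 1]]])
    depth_bounds = np.concatenate([grid.depth_bounds[iz], [grid.depth_bounds[iz[-1] + 1]]])
    sub = make_ocean_grid(
        grid.lon_bounds, lat_bounds, depth_bounds, grid.bathymetry[iy, :]
    )

    def cut(a):
        return None if a is None else a[:, iz][:, :, iy, :].copy()

    out = FieldSet(
        fields.period_label,
        fields.scenario_label,
        cut(fields.theta),
        cut(fields.sp),
        cut(fields.o2_conc),
        cut(fields.t_insitu),
        cut(fields.po2),
    )
    return out, sub


def shelf_mask(grid: OceanGrid) -> np.ndarray:
    """Continental-shelf mask: flood fill of bathymetry <= 1000 m from the coast.

    The Antarctic boundary is the southernmost latitude row containing wet
    cells; the shelf is the connected component (4-connectivity, periodic in
    longitude) of shallow wet cells reachable from that row.  A shallow bank
    separated from the coast by deep water is therefore not shelf.
    """
    wet = grid.bathymetry > 0
    shallow = wet & (grid.bathymetry <= SHELF_ISOBATH_M)
    south_rows = np.flatnonzero(wet.any(axis=1))
    if south_rows.size == 0:
        raise ValueError("no wet cell in any latitude row")
    # lat_centers may be ascending or descending; southernmost = minimum lat
    south_row = south_rows[np.argmin(grid.lat_centers[south_rows])]
    if not shallow[south_row].any():
        raise ValueError("no shallow wet cell in the southernmost wet row")

    labels, n = ndimage.label(shallow)
    if n == 0:
        return np.zeros_like(shallow)
    # merge labels across the periodic longitude seam
    parent = np.arange(n + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    left, right = labels[:, 0], labels[:, -1]
    for a, b in zip(left, right):
        if a and b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.array([find(i) for i in range(n + 1)])
    merged = roots[labels]
    seeds = set(np.unique(merged[south_row][shallow[south_row]])) - {0}
    return np.isin(merged, sorted(seeds))


def ccamlr_masks(grid: OceanGrid, shelf: Optional[np.ndarray] = None) -> RegionMasks:
    """Longitude-sector masks for CCAMLR Convention Areas 48 / 58 / 88.

    Area 48 (Weddell Sea) spans 70W-30E, Area 58 (East Antarctica) 30E-150E,
    Area 88 (Ross/Amundsen/Bellingshausen) the remainder 150E-70W.  Sectors
    partition the wet domain.
    """
    lon = grid.lon_centers
    if np.any(lon < -180.0) or np.any(lon >= 180.0):
        raise ValueError("longitudes must lie in [-180, 180)")
    wet = grid.bathymetry > 0
    in48 = (lon >= CCAMLR_BOUNDS["area48"][0]) & (lon < CCAMLR_BOUNDS["area48"][1])
    in58 = (lon >= CCAMLR_BOUNDS["area58"][0]) & (lon < CCAMLR_BOUNDS["area58"][1])
    in88 = ~(in48 | in58)
    if shelf is None:
        shelf = shelf_mask(grid)
    return RegionMasks(
        domain=wet,
        shelf=shelf & wet,
        area48=wet & in48[None, :],
        area58=wet & in58[None, :],
        area88=wet & in88[None, :],
    )


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style, NetCDF3 classic via the scipy backend)
# ---------------------------------------------------------------------------

_VAR_UNITS = {
    "thetao": "degC",
    "so": "1",
    "o2": "mmol m-3",
    "to_insitu": "degC",
    "po2": "mbar",
}
_FIELD_TO_VAR = {
    "theta": "thetao",
    "sp": "so",
    "o2_conc": "o2",
    "t_insitu": "to_insitu",
    "po2": "po2",
}


def _grid_coords(grid: OceanGrid, ntime: int) -> dict:
    return {
        "time": np.arange(ntime),
        "depth": ("depth", grid.depth_centers, {"units": "m", "positive": "down"}),
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
    }


def write_fields(path, fields: FieldSet, grid: OceanGrid) -> None:
    """Write a FieldSet plus grid geometry to a CF-style NetCDF file."""
    data = {}
    for attr, var in _FIELD_TO_VAR.items():
        a = getattr(fields, attr)
        if a is not None:
            data[var] = (("time", "depth", "lat", "lon"), a, {"units": _VAR_UNITS[var]})
    data["cell_area"] = (("lat", "lon"), grid.cell_area, {"units": "km2"})
    data["bathymetry"] = (("lat", "lon"), grid.bathymetry, {"units": "m"})
    data["depth_bnds"] = (("depth_edge",), grid.depth_bounds, {"units": "m"})
    data["lat_bnds"] = (("lat_edge",), grid.lat_bounds, {"units": "degrees_north"})
    data["lon_bnds"] = (("lon_edge",), grid.lon_bounds, {"units": "degrees_east"})
    ds = xr.Dataset(
        data,
        coords=_grid_coords(grid, fields.n_time),
        attrs={
            "Conventions": "CF-1.8",
            "period_label": fields.period_label,
            "scenario_label": fields.scenario_label,
        },
    )
    ds.to_netcdf(path, engine="scipy")


_UNIT_ALIASES = {
    "thetao": {"degc", "celsius", "degrees_celsius", "deg_c", "c"},
    "to_insitu": {"degc", "celsius", "degrees_celsius", "deg_c", "c"},
    "so": {"1", "psu", "", "1e-3"},
    "o2": {"mmol m-3", "mmol/m3", "mmol/m^3", "mmol m^-3"},
    "po2": {"mbar", "hpa"},
}


def load_fields(path, variable_map: Optional[dict] = None) -> tuple[FieldSet, OceanGrid]:
    """Read a FieldSet and its grid from NetCDF.

    ``variable_map`` maps canonical names (thetao, so, o2, ...) to the names
    used in the file.  Depth axes stored negative-up are converted to positive
    down.  Unknown units raise rather than silently mis-scale.
    """
    variable_map = variable_map or {}
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for coord in ("lon", "lat", "depth", "time"):
        if coord not in ds.dims and coord not in ds.coords:
            raise ValueError(f"file {path} lacks coordinate '{coord}'")

    depth = ds["depth"].values.astype(float)
    flip = False
    if np.all(depth <= 0) and np.any(depth < 0):
        depth = -depth
        flip = True
    if depth.size > 1 and depth[0] > depth[-1]:
        order = slice(None, None, -1)
    else:
        order = slice(None)

    def pick(canon, required):
        name = variable_map.get(canon, canon)
        if name not in ds:
            if required:
                raise ValueError(f"file {path} is missing required variable '{name}' ({canon})")
            return None
        da = ds[name]
        units = str(da.attrs.get("units", "")).lower()
        allowed = _UNIT_ALIASES.get(canon)
        if allowed is not None and units and units not in allowed:
            raise ValueError(f"variable '{name}': unknown units '{units}'")
        a = da.values.astype(float)
        return a[:, order, :, :]

    theta = pick("thetao", True)
    sp = pick("so", True)
    o2 = pick("o2", True)
    t_insitu = pick("to_insitu", False)
    po2 = pick("po2", False)
    _ = flip

    depth = depth[order]
    if "depth_bnds" in ds:
        depth_bounds = np.abs(ds["depth_bnds"].values.astype(float))
        depth_bounds = np.sort(depth_bounds)
    else:
        mid = 0.5 * (depth[:-1] + depth[1:])
        depth_bounds = np.concatenate([[0.0], mid, [depth[-1] + (depth[-1] - mid[-1])]])
    lat = ds["lat"].values.astype(float)
    lon = ds["lon"].values.astype(float)
    if "lat_bnds" in ds:
        lat_bounds = ds["lat_bnds"].values.astype(float)
    else:
        dl = np.diff(lat).mean() if lat.size > 1 else 1.0
        lat_bounds = np.concatenate([lat - dl / 2, [lat[-1] + dl / 2]])
    if "lon_bnds" in ds:
        lon_bounds = ds["lon_bnds"].values.astype(float)
    else:
        dl = np.diff(lon).mean() if lon.size > 1 else 1.0
        lon_bounds = np.concatenate([lon - dl / 2, [lon[-1] + dl / 2]])
    if "bathymetry" in ds:
        bathy = ds["bathymetry"].values.astype(float)
    else:
        bathy = np.full((lat.size, lon.size), depth_bounds[-1])

    if "cell_area" in ds:
        area = ds["cell_area"].values.astype(float)
    else:
        dlam = np.deg2rad(np.diff(lon_bounds))
        band = EARTH_RADIUS_KM**2 * np.diff(np.sin(np.deg2rad(lat_bounds)))
        area = band[:, None] * dlam[None, :]
    grid = OceanGrid(
        lon_centers=lon,
        lat_centers=lat,
        lon_bounds=lon_bounds,
        lat_bounds=lat_bounds,
        depth_centers=depth,
        depth_bounds=depth_bounds,
        cell_area=area,
        bathymetry=bathy,
    )
    fields = FieldSet(
        period_label=str(ds.attrs.get("period_label", "")),
        scenario_label=str(ds.attrs.get("scenario_label", "")),
        theta=theta,
        sp=sp,
        o2_conc=o2,
        t_insitu=t_insitu,
        po2=po2,
    )
    return fields, grid


def write_mask(path, mask: np.ndarray, grid: OceanGrid, name: str = "mask", **attrs) -> None:
    """Write a 2-D or 3-D boolean mask as a flagged byte NetCDF variable."""
    mask = np.asarray(mask)
    dims = ("depth", "lat", "lon") if mask.ndim == 3 else ("lat", "lon")
    coords = {
        "depth": ("depth", grid.depth_centers, {"units": "m", "positive": "down"}),
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
    }
    if mask.ndim == 2:
        coords.pop("depth")
    ds = xr.Dataset(
        {name: (dims, mask.astype(np.int8), {"flag_values": [0, 1], "flag_meanings": "absent present"})},
        coords=coords,
        attrs=dict(attrs),
    )
    ds.to_netcdf(path, engine="scipy")


def load_mask(path, name: str = "mask") -> np.ndarray:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds[name].values.astype(bool)


def region_volume_table(grid: OceanGrid, masks: RegionMasks) -> pd.DataFrame:
    """Per-region, per-depth-level wet volume table (region, depth_level_m, volume_km3)."""
    rows = []
    regions = {
        "domain": masks.domain,
        "shelf": masks.shelf,
        "area48": masks.area48,
        "area58": masks.area58,
        "area88": masks.area88,
    }
    for region, m2d in regions.items():
        vol = np.where(m2d[None, :, :], grid.cell_volume, 0.0).sum(axis=(1, 2))
        for z, v in zip(grid.depth_centers, vol):
            rows.append({"region": region, "depth_level_m": z, "volume_km3": v})
    return pd.DataFrame(rows)
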