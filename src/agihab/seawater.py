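"""Seawater state conversions.

Elementwise conversions needed before any habitat-viability math can run:

* potential -> in situ temperature (UNESCO adiabatic-lapse-rate integration,
  Bryden 1973 polynomial, Fofonoff & Millard 1983 Runge-Kutta scheme),
* in situ density (EOS-80 international equation of state),
* oxygen solubility (Garcia & Gordon 1992, Benson-Krause coefficients),
* seawater vapor pressure (Weiss & Price 1980),
* partial pressure of oxygen from molal concentration.

All functions are pure, operate on scalars or numpy arrays of any shape, and
propagate NaN. Temperatures cross this interface in degrees Celsius, salinity
is practical salinity (unitless), depth is metres positive down.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pressure_from_depth",
    "adiabatic_lapse_rate",
    "insitu_temperature",
    "insitu_density",
    "o2_saturation",
    "vapor_pressure_h2o",
    "o2_molal_from_volumetric",
    "o2_volumetric_from_molal",
    "compute_po2",
    "add_derived_fields",
]

#: mole fraction of O2 in dry air
X_O2 = 0.20946
#: standard atmospheric pressure in mbar
P_ATM_MBAR = 1013.25

_THETA_RANGE = (-3.0, 40.0)
_SP_RANGE = (0.0, 42.0)


def _check_ranges(theta, sp):
    theta = np.asarray(theta, dtype=float)
    sp = np.asarray(sp, dtype=float)
    with np.errstate(invalid="ignore"):
        bad_t = (theta < _THETA_RANGE[0]) | (theta > _THETA_RANGE[1])
        bad_s = (sp < _SP_RANGE[0]) | (sp > _SP_RANGE[1])
    if np.any(bad_t):
        raise ValueError(
            f"temperature outside plausible range {_THETA_RANGE}: "
            f"min={np.nanmin(theta)}, max={np.nanmax(theta)}"
        )
    if np.any(bad_s):
        raise ValueError(
            f"practical salinity outside plausible range {_SP_RANGE}: "
            f"min={np.nanmin(sp)}, max={np.nanmax(sp)}"
        )
    return theta, sp


def pressure_from_depth(depth, lat):
    """Sea pressure (dbar) from depth (m, positive down) and latitude.

    Saunders (1981) latitude-dependent fit; adequate to a few dbar over the
    0-3500 m range handled here.
    """
    depth = np.asarray(depth, dtype=float)
    lat = np.asarray(lat, dtype=float)
    sin2 = np.sin(np.deg2rad(lat)) ** 2
    c1 = (5.92 + 5.25 * sin2) * 1e-3
    c2 = 2.21e-6
    return (1.0 - c1 - np.sqrt((1.0 - c1) ** 2 - 4.0 * c2 * depth)) / (2.0 * c2)


def adiabatic_lapse_rate(t, sp, p):
    """Adiabatic temperature gradient (deg C / dbar), Bryden (1973)."""
    t = np.asarray(t, dtype=float)
    sp = np.asarray(sp, dtype=float)
    p = np.asarray(p, dtype=float)
    ds = sp - 35.0
    atg = (
        3.5803e-5
        + 8.5258e-6 * t
        - 6.836e-8 * t**2
        + 6.6228e-10 * t**3
        + (1.8932e-6 - 4.2393e-8 * t) * ds
        + (1.8741e-8 - 6.7795e-10 * t + 8.733e-12 * t**2 - 5.4481e-14 * t**3) * p
        + (-1.1351e-10 + 2.7759e-12 * t) * ds * p
        + (-4.6206e-13 + 1.8676e-14 * t - 2.1687e-16 * t**2) * p**2
    )
    return atg


def _theta_rk(sp, t0, p0, pr):
    """UNESCO 4-step Runge-Kutta integration of the lapse rate from p0 to pr.

    Returns the temperature the parcel attains when moved adiabatically from
    pressure p0 to pressure pr.  This is the Fofonoff & Millard (1983)
    potential-temperature scheme; with (p0=0, pr=p) it yields in situ
    temperature from potential temperature.
    """
    dp = pr - p0
    t = np.asarray(t0, dtype=float).copy()
    q = np.zeros_like(t)

    dt = dp * adiabatic_lapse_rate(t, sp, p0)
    t = t + 0.5 * dt
    q = dt

    dt = dp * adiabatic_lapse_rate(t, sp, p0 + 0.5 * dp)
    t = t + (1.0 - 1.0 / np.sqrt(2.0)) * (dt - q)
    q = (2.0 - np.sqrt(2.0)) * dt + (-2.0 + 3.0 / np.sqrt(2.0)) * q

    dt = dp * adiabatic_lapse_rate(t, sp, p0 + 0.5 * dp)
    t = t + (1.0 + 1.0 / np.sqrt(2.0)) * (dt - q)
    q = (2.0 + np.sqrt(2.0)) * dt + (-2.0 - 3.0 / np.sqrt(2.0)) * q

    dt = dp * adiabatic_lapse_rate(t, sp, p0 + dp)
    return t + (dt - 2.0 * q) / 6.0


def insitu_temperature(theta, sp, depth, lat):
    """In situ temperature (deg C) from potential temperature.

    Moves a parcel adiabatically from the surface reference (0 dbar) down to
    the local pressure; at depth 0 the result equals ``theta`` exactly.
    """
    theta, sp = _check_ranges(theta, sp)
    p = pressure_from_depth(depth, lat)
    theta, sp, p = np.broadcast_arrays(theta, sp, p)
    return _theta_rk(np.asarray(sp, float), np.asarray(theta, float), 0.0, np.asarray(p, float))


def insitu_density(t_insitu, sp, depth, lat):
    """In situ density (kg m-3), EOS-80 international equation of state."""
    t, sp = _check_ranges(t_insitu, sp)
    p = pressure_from_depth(depth, lat)
    t, sp, p = np.broadcast_arrays(t, sp, p)
    t = np.asarray(t, float)
    s = np.asarray(sp, float)
    pb = np.asarray(p, float) / 10.0  # dbar -> bar

    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    s15 = s * np.sqrt(np.maximum(s, 0.0))
    rho0 = rho_w + a * s + b * s15 + c * s**2

    kw = (
        19652.21
        + 148.4206 * t
        - 2.327105 * t**2
        + 1.360477e-2 * t**3
        - 5.155288e-5 * t**4
    )
    k0 = (
        kw
        + s * (54.6746 - 0.603459 * t + 1.09987e-2 * t**2 - 6.1670e-5 * t**3)
        + s15 * (7.944e-2 + 1.6483e-2 * t - 5.3009e-4 * t**2)
    )
    aw = 3.239908 + 1.43713e-3 * t + 1.16092e-4 * t**2 - 5.77905e-7 * t**3
    ak = aw + s * (2.2838e-3 - 1.0981e-5 * t - 1.6078e-6 * t**2) + 1.91075e-4 * s15
    bw = 8.50935e-5 - 6.12293e-6 * t + 5.2787e-8 * t**2
    bk = bw + s * (-9.9348e-7 + 2.0816e-8 * t + 9.1697e-10 * t**2)
    k = k0 + ak * pb + bk * pb**2
    return rho0 / (1.0 - pb / k)


def o2_saturation(t_insitu, sp):
    """Oxygen solubility at 1 atm moist air, in umol kg-1.

    Garcia & Gordon (1992) fit to the Benson & Krause data.
    """
    t, s = _check_ranges(t_insitu, sp)
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    ts = np.log((298.15 - t) / (273.15 + t))
    a = (
        5.80871
        + 3.20291 * ts
        + 4.17887 * ts**2
        + 5.10006 * ts**3
        - 9.86643e-2 * ts**4
        + 3.80369 * ts**5
    )
    b = -7.01577e-3 - 7.70028e-3 * ts - 1.13864e-2 * ts**2 - 9.51519e-3 * ts**3
    c0 = -2.75915e-7
    return np.exp(a + s * b + c0 * s**2)


def vapor_pressure_h2o(t_insitu, sp):
    """Saturation vapor pressure of seawater (mbar), Weiss & Price (1980)."""
    t, s = _check_ranges(t_insitu, sp)
    tk = np.asarray(t, float) + 273.15
    ln_p_atm = (
        24.4543
        - 67.4509 * (100.0 / tk)
        - 4.8489 * np.log(tk / 100.0)
        - 0.000544 * np.asarray(s, float)
    )
    return np.exp(ln_p_atm) * P_ATM_MBAR


def o2_molal_from_volumetric(o2_conc, rho):
    """mmol m-3 -> mol kg-1 using in situ density (kg m-3)."""
    return np.asarray(o2_conc, float) * 1e-3 / np.asarray(rho, float)


def o2_volumetric_from_molal(o2_molal, rho):
    """mol kg-1 -> mmol m-3 using in situ density (kg m-3)."""
    return np.asarray(o2_molal, float) * 1e3 * np.asarray(rho, float)


def compute_po2(o2_molal, t_insitu, sp):
    """Partial pressure of oxygen (mbar) from molal O2 concentration.

    Saturation-fraction formulation: the fraction of the Garcia-Gordon
    equilibrium concentration, times the O2 mole fraction of dry air, times
    dry-air pressure (total minus water vapor).  Hydrostatic pressure is
    deliberately ignored, as is conventional for metabolic indices.
    """
    o2_molal = np.asarray(o2_molal, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(o2_molal < 0):
            raise ValueError("negative oxygen concentration")
    sat_molal = o2_saturation(t_insitu, sp) * 1e-6  # umol/kg -> mol/kg
    dry_air = P_ATM_MBAR - vapor_pressure_h2o(t_insitu, sp)
    return o2_molal / sat_molal * X_O2 * dry_air


def add_derived_fields(fields, grid):
    """Fill ``t_insitu`` and ``po2`` on a FieldSet in place (and return it).

    Broadcasts the grid's depth/latitude over the (time, depth, lat, lon)
    field arrays; land cells (NaN) propagate.
    """
    depth = grid.depth_centers[None, :, None, None]
    lat = grid.lat_centers[None, None, :, None]
    fields.t_insitu = insitu_temperature(fields.theta, fields.sp, depth, lat)
    rho = insitu_density(fields.t_insitu, fields.sp, depth, lat)
    molal = o2_molal_from_volumetric(fields.o2_conc, rho)
    # land is NaN; clip stray negatives from additive perturbations to zero
    molal = np.where(np.isnan(molal), np.nan, np.maximum(molal, 0.0))
    fields.po2 = compute_po2(molal, fields.t_insitu, fields.sp)
    return fields
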