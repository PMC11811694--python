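# Methods

## Model

The aerobic growth index (AGI) treats habitat viability as an oxygen
supply/demand balance. Supply is the ambient partial pressure of oxygen
pO2 (mbar); demand is a species-specific reference pressure `pO2thr`
modulated by an Arrhenius-type temperature response:

    AGI = pO2 / ( pO2thr · (1/3)^(1−d) · exp( (j2−j1)/Tpref − (j2−j1)/T ) )

with `T`, `Tpref` in Kelvin. `j1 = 4500 K` and `j2 = 8000 K` are the
anabolism and catabolism activation energies divided by the Boltzmann
constant and `d = 0.7` the metabolic scaling coefficient; all three are
fixed constants of the formulation, exposed through `AGIParams` for
sensitivity runs but frozen by default. The demand mass factor is written
with an explicit base (`mass_ratio_base = 1/3`) so the identity
`AGI(Tpref, pO2thr) = 3^(1−d) = 3^0.3` holds exactly and is asserted to
machine precision in the tests. Because every species-specific factor of
the demand term cancels in a future/historical ratio, the relative change
`AGIrel = 100·(AGI_f/AGI_h − 1)` is species-independent; the pipeline
exploits this and computes one AGIrel field per scenario.

Assumptions inherited from the index: no acclimation or adaptation, no
body-size resolution, habitat fixed at its contemporary 3-D extent (the
index can only shrink or locally re-open habitat inside that envelope, not
extend it), and drivers restricted to temperature and oxygen — sea ice,
circulation and acidification are outside its scope.

## Thresholds and viability

- `Tpref`: volume-weighted 50th percentile of monthly climatological
  in situ temperature inside the species' 3-D habitat.
- `pO2thr`: volume-weighted 10th percentile of monthly in-habitat pO2.
- `AGIcrit`: volume-weighted 10th percentile of monthly in-habitat AGI.

The weighted percentile uses an empirical-CDF, lower-value rule: the
smallest sample value whose cumulative normalized weight reaches the
requested fraction. No interpolation — the rule is reproducible,
order-independent after tie aggregation, and exact on ties. Each of the 12
climatological months contributes one sample per habitat cell, all at the
cell's volume weight (months are not length-weighted).

Viability uses the strict inequality `AGI > AGIcrit`; boundary cells are
excluded. The baseline viable volume Ω is evaluated on the annual mean of
the derived monthly historical fields, so that historical and future
(annual-mean) volumes are like-for-like; by the percentile construction a
zero-seasonality climatology then yields Ω ≈ 0.9 × habitat volume, up to
the volume fraction of a single cell — a property the acceptance tests
check. Overlap Φ is the volume of the intersection of two viable masks,
reported whole-habitat, on the continental shelf, per CCAMLR area, and for
the depth intervals 0–400 / 400–700 / 700–1000 / 1000–3500 m.

## Seawater conversions

Potential temperature is converted to in situ temperature by integrating
the Bryden (1973) adiabatic lapse rate from the surface to the local
pressure with the Fofonoff & Millard (1983) Runge-Kutta scheme; pressure
comes from the Saunders (1981) depth/latitude fit. In situ density uses
the EOS-80 international equation of state, oxygen solubility the
Garcia & Gordon (1992) fit to the Benson–Krause data, and seawater vapor
pressure the Weiss & Price (1980) formula. pO2 is the saturation fraction
times the O2 mole fraction of dry air (0.20946) times dry-air pressure
(1013.25 mbar minus vapor pressure); hydrostatic pressure is ignored in
the pO2 itself, as is conventional for metabolic indices. EOS-80/UNESCO
was chosen over TEOS-10 as it matches the legacy seawater toolkit lineage
of this analysis type; differences are far below the analysis'
sensitivity, and the formulation is isolated behind `agihab.seawater`.
Oracles: an independent `solve_ivp` integration of the lapse rate, and
published check values (fresh water 999.842594 kg m⁻³; O2 solubility
274.61 µmol kg⁻¹ at 10 °C, S=35; saturated pO2 ≈ 211 mbar at 0 °C).

## Habitats

2-D occurrence-probability maps are thresholded (threshold 0 means
strictly positive probability; positive thresholds are inclusive, so the
printed squid suitability thresholds 0.228/0.281/0.121 keep boundary
cells), regridded to the analysis grid by largest area fraction (per-cell
majority vote on spherical band areas via sin-latitude differences; exact
50/50 ties resolve to presence), and extruded over the species' depth
range by level-centre membership in the closed interval — centres avoid
double counting at layer boundaries. Habitats are intersected with the
wet mask and the 3185 m analysis cap; source presence outside the domain
(north of 45°S) is truncated and the truncated fraction logged. The
packaged 29-species table carries the study species' depth ranges and
published thresholds at occurrence thresholds 0 and 0.8.

## Grid and regions

The analysis grid is regular lon-lat-depth with partial bottom cells: a
layer's wet thickness is clipped at the bathymetry, so summed cell volumes
equal the bathymetric volume and volume totals (the currency of Ω and Φ)
carry minimal discretization bias. The continental shelf is the connected
component of bathymetry ≤ 1000 m reachable from the southernmost wet row
(4-connectivity, periodic in longitude), so shallow offshore banks
separated by deep trenches are excluded. CCAMLR areas 48/58/88 are pure
longitude sectors at 70°W–30°E, 30°E–150°E and 150°E–70°W; the named
areas have no published analytic boundaries, so standard sector longitudes
are used. Missing values are NaN throughout, never zero.

## Scenario pipeline

Future annual fields of in situ temperature and oxygen concentration are
drift-corrected by subtracting the control run's change over the same
interval; pO2 is then recomputed from the corrected concentration and
temperature (correction applied after the potential→in situ conversion; the
difference is second order). Attribution holds one driver at historical
levels: temperature-only pairs future T with historical pO2; oxygen-only
recomputes pO2 from future O2 with historical T and S. Profile curves are
volume-weighted in-habitat means per depth level; prey richness is
area-weighted per level, counting prey viable at each cell of the
predator's viable mask. Percent changes use the historical value as
denominator; strata with zero historical volume are reported as undefined
(NaN), never 0 or ∞.

## Synthetic generator

`agihab.synth` emulates the statistical structure the analysis assumes,
not ocean dynamics: a meridional surface temperature gradient (−1.8 °C at
the coast to 4 °C at 45°S), a seasonal cycle confined to the top ~200 m, a
warm CDW-like subsurface anomaly near 500 m, oxygen decreasing from
~340 mmol m⁻³ at the surface to a mid-depth minimum, a 500 m shelf band
south of a ~3300 m basin, and species bands as smooth probability bumps
(plateau ~0.95, so both the 0 and 0.8 occurrence thresholds are
meaningful). Scenario forcing at full scale applies 1.2 °C
surface-intensified warming (250 m e-folding) with a 0.3 °C subsurface
maximum, an upper-ocean oxygen gain of 12 mmol m⁻³ and a loss of
20 mmol m⁻³ peaking at 600 m (width 180 m), chosen to mirror the reported
projection magnitudes (surface warming up to ~1.2 °C, upper-ocean pO2
gains of a few mbar, subsurface losses peaking below 500 m); scenario
scales 0.25/0.5/0.75/1.0 create a monotone forcing ladder for ordering
tests, not a claim about real scenario spacing. Noise is purely spatial
and shared by all months, so a zero-seasonality configuration has
bit-identical months — the configuration the percentile-construction check
relies on. All randomness flows from the single seeded generator; the
default grid is 4° lon × ~2° lat × 20 stretched levels to 3500 m, sized so
the full pipeline runs in seconds while the four reporting depth intervals
each contain several levels.

What passing tests on synthetic data do **not** show: skill on real model
output (no mesoscale structure, no water-mass pathways, no land, no ice
shelf cavities — the bathymetry surface is the only floor), nor the
realism of any particular species' thresholds.

## Numerical choices and limitations

- Percentile rule and strict viability inequality as above; ties at the
  AGIcrit boundary excluded deterministically.
- The annual mean of derived monthly in situ fields differs from fields
  derived from the annual-mean state at order 10⁻⁶ °C (nonlinearity of the
  conversions over the seasonal cycle); a zero-forcing scenario therefore
  reports changes that are zero to that order, not bitwise zero.
- Largest-area-fraction regridding uses plate-carrée overlap with exact
  spherical band weighting, not spherical polygon clipping; adequate at
  the target resolutions.
- Future-period labels (2091–2100 / 2081–2100 / 2098–2100) are a config
  switch over the same pipeline; the synthetic generator treats them as
  labels only.
- Curvilinear and unstructured source meshes are out of scope; inputs must
  be on (or interpolated to) a regular lon-lat grid.
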