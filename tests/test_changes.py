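"""Drift correction, attribution, profiles, and change reports."""

import numpy as np
import pandas as pd
import pytest

from agihab import (
    FieldSet,
    SpeciesRecord,
    SpeciesRegistry,
    SpeciesThresholds,
    ViabilityResult,
    agi,
    attribute_change,
    drift_correct,
    habitat_profile,
    omega_change_report,
    phi_change_report,
    prey_richness,
    project_scenarios,
    viable_volume,
)
from agihab.agi import agi_rel
from agihab.changes import ScenarioSet


class TestDriftCorrect:
    def test_arithmetic(self):
        assert drift_correct(5.0, 4.0, 3.0) == 4.0

    def test_zero_drift_identity(self):
        x = np.random.default_rng(0).normal(size=(3, 4))
        c = np.random.default_rng(1).normal(size=(3, 4))
        np.testing.assert_array_equal(drift_correct(x, c, c), x)

    def test_control_self_correction(self):
        ch = np.random.default_rng(2).normal(size=(5,))
        cf = ch + 0.7
        np.testing.assert_allclose(drift_correct(cf, cf, ch), ch, rtol=1e-12)

    def test_linear_in_field(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 6))
        cf, ch = rng.normal(size=(2, 6))
        lhs = drift_correct(a + b, cf, ch)
        rhs = drift_correct(a, cf, ch) + drift_correct(b, cf, ch) - drift_correct(
            np.zeros(6), cf, ch
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            drift_correct(np.zeros(3), np.zeros(4), np.zeros(4))


def _annual(grid, t, o2, sp=34.5):
    shape = (1,) + grid.shape
    from agihab import seawater

    fs = FieldSet(
        "p", "s", np.full(shape, t), np.full(shape, sp), np.full(shape, o2)
    )
    seawater.add_derived_fields(fs, grid)
    return fs


class TestAttribution:
    def test_no_change_all_modes(self, grid_factory):
        g = grid_factory(np.full((2, 3), 800.0))
        hist = _annual(g, 0.0, 300.0)
        fut = _annual(g, 0.0, 300.0)
        thr = SpeciesThresholds(t_pref=0.0, po2_thr=120.0)
        for mode in ("temperature_only", "oxygen_only", "both"):
            t, p = attribute_change(hist, fut, mode, g)
            rel = agi_rel(agi(t, p, thr), agi(hist.t_insitu, hist.po2, thr))
            wet = g.wet_mask[None]
            np.testing.assert_allclose(rel[wet], 0.0, atol=1e-9)

    def test_oxygen_only_ignores_warming(self, grid_factory):
        g = grid_factory(np.full((2, 3), 800.0))
        hist = _annual(g, 0.0, 300.0)
        fut = _annual(g, 2.0, 300.0)  # pure warming, oxygen unchanged
        thr = SpeciesThresholds(t_pref=0.0, po2_thr=120.0)
        t, p = attribute_change(hist, fut, "oxygen_only", g)
        rel = agi_rel(agi(t, p, thr), agi(hist.t_insitu, hist.po2, thr))
        np.testing.assert_allclose(rel[g.wet_mask[None]], 0.0, atol=1e-9)

    def test_temperature_only_ignores_deoxygenation(self, grid_factory):
        g = grid_factory(np.full((2, 3), 800.0))
        hist = _annual(g, 0.0, 300.0)
        fut = _annual(g, 0.0, 250.0)  # pure deoxygenation
        thr = SpeciesThresholds(t_pref=0.0, po2_thr=120.0)
        t, p = attribute_change(hist, fut, "temperature_only", g)
        rel = agi_rel(agi(t, p, thr), agi(hist.t_insitu, hist.po2, thr))
        np.testing.assert_allclose(rel[g.wet_mask[None]], 0.0, atol=1e-9)

    def test_ratio_factorization_with_supplied_po2(self):
        # when pO2 fields are supplied directly, the T-only and O2-only AGI
        # ratios multiply to the combined ratio (demand and supply factorize)
        thr = SpeciesThresholds(t_pref=0.5, po2_thr=130.0)
        rng = np.random.default_rng(4)
        t_h, po2_h = rng.uniform(-1, 3, 20), rng.uniform(120, 200, 20)
        t_f, po2_f = t_h + rng.uniform(0, 1.5, 20), po2_h * rng.uniform(0.85, 1.05, 20)
        base = agi(t_h, po2_h, thr)
        r_t = agi(t_f, po2_h, thr) / base
        r_o = agi(t_h, po2_f, thr) / base
        r_both = agi(t_f, po2_f, thr) / base
        np.testing.assert_allclose(r_t * r_o, r_both, rtol=1e-12)

    def test_unknown_mode(self, grid_factory):
        g = grid_factory(np.full((2, 3), 800.0))
        hist = _annual(g, 0.0, 300.0)
        with pytest.raises(ValueError):
            attribute_change(hist, hist, "carbonate_only", g)


class TestHabitatProfile:
    def test_constant_field(self, grid_factory):
        g = grid_factory(np.full((2, 3), 800.0))
        prof = habitat_profile(np.full(g.shape, 3.3), g.wet_mask, g)
        wet_levels = g.wet_mask.any(axis=(1, 2))
        np.testing.assert_allclose(prof[wet_levels], 3.3)
        assert np.isnan(prof[~wet_levels]).all()

    def test_volume_weighting(self, grid_factory):
        g = grid_factory(np.array([[500.0, 500.0]]), depth_bounds=(0.0, 100.0))
        g.cell_volume = np.array([[[1.0, 3.0]]])
        field = np.array([[[0.0, 4.0]]])
        prof = habitat_profile(field, np.ones(g.shape, bool), g)
        assert prof[0] == pytest.approx(3.0)

    def test_equal_volume_mean(self, grid_factory):
        g = grid_factory(np.array([[500.0, 500.0]]), depth_bounds=(0.0, 100.0))
        g.cell_volume = np.array([[[2.0, 2.0]]])
        field = np.array([[[0.0, 2.0]]])
        prof = habitat_profile(field, np.ones(g.shape, bool), g)
        assert prof[0] == pytest.approx(1.0)


def _viab(grid, mask):
    vol = np.where(mask, grid.cell_volume, 0.0)
    return ViabilityResult(
        agi_field=np.where(mask, 2.0, 0.5),
        viable_mask=mask,
        omega_total=float(vol.sum()),
        omega_by_level=vol.sum(axis=(1, 2)),
    )


def _registry_two(grid):
    recs = [
        SpeciesRecord(species_id=1, name="pred", min_depth=0, max_depth=3500),
        SpeciesRecord(species_id=2, name="prey", min_depth=0, max_depth=3500),
    ]
    for r in recs:
        r.habitat3d = grid.wet_mask
    return SpeciesRegistry(records=recs, predator_id=1)


class TestOmegaReport:
    def test_no_change_and_halving(self, grid_factory):
        g = grid_factory(np.full((2, 2), 800.0))
        reg = _registry_two(g)
        full = _viab(g, g.wet_mask)
        hist = {1: full, 2: full}
        half_mask = g.wet_mask.copy()
        half_mask[:, :, 0] = False
        # build a half-volume future by symmetric columns (equal areas up to lat)
        fut_v = _viab(g, half_mask)
        fut = {1: full, 2: fut_v}
        tab = omega_change_report(reg, hist, fut, g).set_index("species_id")
        assert tab.loc[1, "omega_change_pct"] == pytest.approx(0.0)
        expect = 100.0 * (fut_v.omega_total - full.omega_total) / full.omega_total
        assert tab.loc[2, "omega_change_pct"] == pytest.approx(expect)

    def test_zero_baseline_flagged_not_divided(self, grid_factory):
        g = grid_factory(np.full((2, 2), 800.0))
        reg = _registry_two(g)
        empty = _viab(g, np.zeros(g.shape, bool))
        tab = omega_change_report(reg, {1: empty, 2: empty}, {1: empty, 2: empty}, g)
        assert tab.omega_change_pct.isna().all()

    def test_decline_fraction_counting(self, report):
        # fraction of prey with >= 10% / >= 5% total decline, from the table
        tab = report.omega_change
        for scen, sub in tab.groupby("scenario"):
            prey = sub[sub.species_id != 1]
            f10 = (prey.omega_change_pct <= -10).mean()
            f5 = (prey.omega_change_pct <= -5).mean()
            assert 0.0 <= f10 <= f5 <= 1.0


class TestPhiReport:
    def test_prey_identical_to_predator_tracks_omega(self, grid_factory):
        g = grid_factory(np.full((2, 3), 800.0))
        reg = _registry_two(g)
        from agihab import ccamlr_masks

        masks = ccamlr_masks(g, shelf=g.bathymetry <= 1000.0)
        full = _viab(g, g.wet_mask)
        shrunk_mask = g.wet_mask.copy()
        shrunk_mask[-1] = False
        shrunk = _viab(g, shrunk_mask)
        tab = phi_change_report(reg, {1: full, 2: full}, {1: shrunk, 2: shrunk}, g, masks)
        omega_change = 100.0 * (shrunk.omega_total - full.omega_total) / full.omega_total
        assert tab.phi_change_pct.iloc[0] == pytest.approx(omega_change)

    def test_disjoint_habitats_zero_overlap(self, grid_factory):
        g = grid_factory(np.full((2, 3), 800.0))
        reg = _registry_two(g)
        from agihab import ccamlr_masks

        masks = ccamlr_masks(g, shelf=g.bathymetry <= 1000.0)
        top = g.wet_mask.copy()
        top[1:] = False
        bot = g.wet_mask & ~top
        tab = phi_change_report(
            reg, {1: _viab(g, top), 2: _viab(g, bot)}, {1: _viab(g, top), 2: _viab(g, bot)}, g, masks
        )
        assert tab.phi_hist_km3.iloc[0] == 0.0
        assert np.isnan(tab.phi_change_pct.iloc[0])

    def test_losing_one_cell(self, grid_factory):
        # 3 cells vol [10,20,30]; hist overlap {c2}; prey loses c2 -> -100%
        g = grid_factory(np.array([[100.0, 200.0, 300.0]]), depth_bounds=(0.0, 300.0))
        g.cell_volume = np.array([[[10.0, 20.0, 30.0]]])
        reg = _registry_two(g)
        from agihab import ccamlr_masks

        masks = ccamlr_masks(g, shelf=g.bathymetry <= 1000.0)
        pred = np.array([[[True, True, False]]])
        prey_h = np.array([[[False, True, True]]])
        prey_f = np.array([[[False, False, True]]])
        tab = phi_change_report(
            reg,
            {1: _viab(g, pred), 2: _viab(g, prey_h)},
            {1: _viab(g, pred), 2: _viab(g, prey_f)},
            g,
            masks,
        )
        assert tab.phi_hist_km3.iloc[0] == pytest.approx(20.0)
        assert tab.phi_change_pct.iloc[0] == pytest.approx(-100.0)


class TestPreyRichness:
    def test_counts_and_exclusion(self, grid_factory):
        g = grid_factory(np.full((2, 3), 800.0))
        recs = [
            SpeciesRecord(species_id=i, name=f"s{i}", min_depth=0, max_depth=3500)
            for i in (1, 2, 3)
        ]
        for r in recs:
            r.habitat3d = g.wet_mask
        reg = SpeciesRegistry(records=recs, predator_id=1)
        from agihab import ccamlr_masks

        masks = ccamlr_masks(g, shelf=g.bathymetry <= 1000.0)
        pred_mask = g.wet_mask.copy()
        pred_mask[:, :, 0] = False  # predator not viable in first column
        viab = {1: _viab(g, pred_mask), 2: _viab(g, g.wet_mask), 3: _viab(g, g.wet_mask)}
        rich, profiles, colmap = prey_richness(reg, viab, masks, g)
        assert np.nanmax(rich) == 2.0
        assert np.isnan(rich[:, :, 0]).all()  # outside predator viable mask
        sub = profiles[profiles.region == "all"].set_index("depth_level_m")
        wet_levels = g.wet_mask.any(axis=(1, 2))
        assert (sub.mean_prey_count[wet_levels] == 2.0).all()

    def test_bounded_by_available_prey(self, bundle, report):
        grid, _, _, registry, _ = bundle
        rich = report.richness_fields["historical"]
        for k, z in enumerate(grid.depth_centers):
            n_possible = sum(
                1 for r in registry.prey if r.min_depth <= z <= r.max_depth
            )
            level = rich[k]
            if np.isfinite(level).any():
                assert np.nanmax(level) <= n_possible

    def test_permutation_invariant(self, grid_factory):
        g = grid_factory(np.full((2, 3), 800.0))
        from agihab import ccamlr_masks

        masks = ccamlr_masks(g, shelf=g.bathymetry <= 1000.0)
        rng = np.random.default_rng(5)
        recs = []
        viab = {}
        for i in range(1, 5):
            r = SpeciesRecord(species_id=i, name=f"s{i}", min_depth=0, max_depth=3500)
            r.habitat3d = g.wet_mask
            recs.append(r)
            viab[i] = _viab(g, g.wet_mask & (rng.random(g.shape) > 0.3))
        reg_fwd = SpeciesRegistry(records=recs, predator_id=1)
        reg_rev = SpeciesRegistry(records=[recs[0]] + recs[:0:-1], predator_id=1)
        rich_a, _, _ = prey_richness(reg_fwd, viab, masks, g)
        rich_b, _, _ = prey_richness(reg_rev, viab, masks, g)
        np.testing.assert_array_equal(rich_a, rich_b)


class TestProjectScenarios:
    def test_agi_rel_profile_species_independent(self, bundle):
        grid, clim, scen, registry, masks = bundle
        rep_a = project_scenarios(scen, registry, grid, masks, scenarios=["ssp585"])
        # recompute AGIrel with a different species' thresholds directly
        from agihab import seawater
        from agihab.changes import _recompute_po2

        ann = clim.annual_mean()
        fut = scen.scenarios["ssp585"].copy()
        seawater.add_derived_fields(fut, grid)
        ctrl_h = scen.control_hist.copy()
        ctrl_f = scen.control_future.copy()
        seawater.add_derived_fields(ctrl_h, grid)
        seawater.add_derived_fields(ctrl_f, grid)
        t_corr = drift_correct(fut.t_insitu, ctrl_f.t_insitu, ctrl_h.t_insitu)
        o2_corr = drift_correct(fut.o2_conc, ctrl_f.o2_conc, ctrl_h.o2_conc)
        po2_corr = _recompute_po2(o2_corr, t_corr, fut.sp, grid)
        thr_other = SpeciesThresholds(t_pref=-1.5, po2_thr=160.0)
        rel_other = agi_rel(
            agi(t_corr[0], po2_corr[0], thr_other), agi(ann.t_insitu[0], ann.po2[0], thr_other)
        )
        rel_report = rep_a.agi_rel_fields["ssp585"]
        ok = np.isfinite(rel_other) & np.isfinite(rel_report)
        np.testing.assert_allclose(rel_other[ok], rel_report[ok], rtol=1e-10, atol=1e-10)

    def test_missing_scenario_listed(self, bundle):
        grid, clim, scen, registry, masks = bundle
        with pytest.raises(ValueError, match="ssp999|ssp585"):
            sub = ScenarioSet(
                historical=scen.historical,
                control_hist=scen.control_hist,
                control_future=scen.control_future,
                scenarios={"ssp126": scen.scenarios["ssp126"]},
            )
            project_scenarios(sub, registry, grid, masks, scenarios=["ssp585"])

    def test_depth_intervals_partition_strata(self, report):
        cols = [c for c in report.phi_change.columns if c.startswith("phi_hist_km3_")]
        assert sorted(cols) == sorted(
            [
                "phi_hist_km3_0_400m",
                "phi_hist_km3_400_700m",
                "phi_hist_km3_700_1000m",
                "phi_hist_km3_1000_3500m",
            ]
        )
        tab = report.phi_change
        np.testing.assert_allclose(
            tab[cols].sum(axis=1), tab.phi_hist_km3, rtol=1e-10, atol=1e-6
        )
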