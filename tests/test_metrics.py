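"""Evaluation stack: gamma index, DVH, dose statistics, plan-quality indices."""

import numpy as np
import pytest
from scipy import ndimage

from cyberbeam.grid import StructureRole, StructureSet, VolumeGrid
from cyberbeam.metrics import (
    DVHCurve,
    GammaCriteria,
    dose_at_volume,
    dose_difference_report,
    dose_quantile,
    dvh,
    gamma_brute_force_mask,
    gamma_pass_mask,
    gamma_passing_rate,
    plan_quality,
    volume_at_dose,
)


def _grid(values, spacing=2.0):
    values = np.asarray(values)
    origin = -(np.array(values.shape) - 1) * spacing / 2
    return VolumeGrid(values, origin, (spacing,) * 3)


def _smooth_field(rng, shape=(16, 16, 16), scale=10.0):
    f = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
    f = f - f.min()
    return scale * f / f.max()


class TestGammaCriteria:
    def test_parse_forms(self):
        for text in ("3mm/3%", "3mm3", " 3 mm / 3 % "):
            c = GammaCriteria.parse(text)
            assert (c.dta, c.dose_pct) == (3.0, 3.0)
        with pytest.raises(ValueError):
            GammaCriteria.parse("not-a-criterion")

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            GammaCriteria(dta=0, dose_pct=3)
        with pytest.raises(ValueError):
            GammaCriteria(dta=3, dose_pct=3, threshold_pct=100)
        with pytest.raises(ValueError):
            GammaCriteria(dta=3, dose_pct=3, normalization="other")


class TestGamma:
    def test_identical_volumes_pass_everywhere(self):
        rng = np.random.default_rng(0)
        ref = _grid(_smooth_field(rng))
        mask = np.ones(ref.shape, bool)
        for crit in ("3mm/3%", "2mm/2%"):
            res = gamma_passing_rate(ref, ref, mask, GammaCriteria.parse(crit))
            assert res.passing_rate == 100.0

    def test_uniform_offset_closed_forms(self):
        ref = _grid(np.full((12, 12, 12), 10.0))
        mask = np.ones(ref.shape, bool)
        crit = GammaCriteria(dta=2.0, dose_pct=2.0)
        # 1 % offset passes 2 %; 5 % offset cannot be rescued by DTA
        ok = gamma_passing_rate(ref, ref.with_values(ref.values * 1.01), mask, crit)
        bad = gamma_passing_rate(ref, ref.with_values(ref.values * 1.05), mask, crit)
        assert ok.passing_rate == 100.0
        assert bad.passing_rate == 0.0

    def test_empty_mask_reports_undefined(self):
        ref = _grid(np.full((8, 8, 8), 10.0))
        res = gamma_passing_rate(ref, ref, np.zeros(ref.shape, bool), GammaCriteria(3, 3))
        assert res.passing_rate is None
        assert res.n_evaluated == 0

    def test_low_dose_threshold_excludes_voxels(self):
        vals = np.zeros((10, 10, 10))
        vals[5, 5, 5] = 100.0
        ref = _grid(vals)
        crit = GammaCriteria(3, 3, threshold_pct=0.5)
        res = gamma_passing_rate(ref, ref, np.ones(ref.shape, bool), crit)
        assert res.n_evaluated == 1

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(42)
        for _ in range(4):
            ref = _grid(_smooth_field(rng, (12, 12, 12)))
            ev = ref.with_values(
                ref.values * rng.uniform(0.95, 1.05)
                + ndimage.gaussian_filter(rng.normal(size=ref.shape), 2.0) * 0.3
            )
            mask = np.ones(ref.shape, bool)
            for crit in (GammaCriteria(3, 2), GammaCriteria(2, 2, threshold_pct=1.0),
                         GammaCriteria(3, 3, normalization="local")):
                fast, inc_f = gamma_pass_mask(ref, ev, mask, crit, subdivisions=1)
                slow, inc_s = gamma_brute_force_mask(ref, ev, mask, crit)
                assert np.array_equal(inc_f, inc_s)
                assert np.array_equal(fast, slow)

    def test_criteria_monotonicity(self):
        rng = np.random.default_rng(3)
        loose, mid, tight = GammaCriteria(3, 3), GammaCriteria(3, 2), GammaCriteria(2, 2)
        for _ in range(10):
            ref = _grid(_smooth_field(rng))
            ev = ref.with_values(ref.values + rng.normal(0, 0.35, ref.shape))
            mask = np.ones(ref.shape, bool)
            r = {c: gamma_passing_rate(ref, ev, mask, c).passing_rate
                 for c in (loose, mid, tight)}
            assert r[tight] <= r[mid] <= r[loose]

    def test_invariance_under_common_translation_and_rescale(self):
        rng = np.random.default_rng(9)
        ref = _grid(_smooth_field(rng))
        ev = ref.with_values(ref.values + rng.normal(0, 0.3, ref.shape))
        mask = np.ones(ref.shape, bool)
        crit = GammaCriteria(3, 2)
        base = gamma_passing_rate(ref, ev, mask, crit).passing_rate
        # rigid translation of both volumes (same values, shifted geometry)
        ref2 = VolumeGrid(ref.values, ref.origin + [13.0, -4.0, 2.5], ref.spacing)
        ev2 = VolumeGrid(ev.values, ev.origin + [13.0, -4.0, 2.5], ev.spacing)
        assert gamma_passing_rate(ref2, ev2, mask, crit).passing_rate == base
        # common dose rescaling with global normalization
        ref3 = ref.with_values(ref.values * 3.7)
        ev3 = ev.with_values(ev.values * 3.7)
        assert gamma_passing_rate(ref3, ev3, mask, crit).passing_rate == pytest.approx(base)


class TestDVH:
    def test_uniform_dose_step(self):
        dose = _grid(np.full((10, 10, 10), 20.0))
        curve = dvh(dose, np.ones(dose.shape, bool), bin_width=0.1)
        assert curve.volume_fraction[curve.dose_edges <= 20.0].min() == 1.0
        assert curve.volume_fraction[curve.dose_edges > 20.0].max() == 0.0

    def test_two_level_structure(self):
        vals = np.full((10, 10, 10), 10.0)
        vals[:5] = 30.0
        dose = _grid(vals)
        curve = dvh(dose, np.ones(dose.shape, bool), bin_width=0.1)
        mid = (curve.dose_edges > 10.0) & (curve.dose_edges <= 30.0)
        assert np.allclose(curve.volume_fraction[mid], 0.5)

    def test_random_curve_properties(self):
        rng = np.random.default_rng(4)
        dose = _grid(rng.uniform(0, 40, (12, 12, 12)))
        curve = dvh(dose, np.ones(dose.shape, bool), bin_width=0.25)
        assert curve.volume_fraction[0] == 1.0
        assert curve.volume_fraction[-1] == 0.0
        assert np.all(np.diff(curve.volume_fraction) <= 1e-12)

    def test_empty_mask_rejected(self):
        dose = _grid(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError):
            dvh(dose, np.zeros(dose.shape, bool))


class TestDoseAtVolume:
    def test_uniform_dose_any_quantile(self):
        dose = _grid(np.full((8, 8, 8), 20.0))
        curve = dvh(dose, np.ones(dose.shape, bool), bin_width=0.1)
        for q in (98, 50, 5):
            assert dose_at_volume(curve, q) == pytest.approx(20.0, abs=0.1)

    def test_step_curve_convention(self):
        vals = np.full((10, 10, 10), 10.0)
        vals[:5] = 30.0
        curve = dvh(_grid(vals), np.ones((10, 10, 10), bool), bin_width=0.1)
        assert dose_at_volume(curve, 50) == pytest.approx(30.0, abs=0.1)
        assert dose_at_volume(curve, 51) == pytest.approx(10.0, abs=0.1)

    def test_quantile_monotonicity(self):
        rng = np.random.default_rng(5)
        curve = dvh(_grid(rng.uniform(0, 40, (10, 10, 10))),
                    np.ones((10, 10, 10), bool), bin_width=0.2)
        d98, d50, d2 = (dose_at_volume(curve, q) for q in (98, 50, 2))
        assert d98 <= d50 <= d2

    def test_volume_dose_consistency(self):
        rng = np.random.default_rng(6)
        curve = dvh(_grid(rng.uniform(0, 40, (12, 12, 12))),
                    np.ones((12, 12, 12), bool), bin_width=0.1)
        for q in (90, 50, 10):
            d = dose_at_volume(curve, q)
            assert volume_at_dose(curve, d) == pytest.approx(q, abs=1.5)

    def test_exact_quantile_convention(self):
        doses = np.array([10.0] * 5 + [30.0] * 5)
        assert dose_quantile(doses, 50) == 30.0
        assert dose_quantile(doses, 51) == 10.0
        assert dose_quantile(np.full(7, 20.0), 95) == 20.0


class TestPlanQuality:
    def test_perfectly_conformal_dose(self):
        target = np.zeros((10, 10, 10), bool)
        target[3:7, 3:7, 3:7] = True
        dose = _grid(np.where(target, 24.0, 0.0))
        q = plan_quality(dose, target, prescription=24.0)
        assert q.nci == pytest.approx(1.0)
        assert q.hi == pytest.approx(1.0)

    def test_equal_external_volume_doubles_nci(self):
        target = np.zeros((12, 12, 12), bool)
        target[1:5, 1:5, 1:5] = True
        external = np.zeros_like(target)
        external[7:11, 7:11, 7:11] = True
        dose = _grid(np.where(target | external, 24.0, 0.0))
        q = plan_quality(dose, target, 24.0)
        assert q.nci == pytest.approx(2.0)

    def test_hand_counted_toy_volumes(self):
        # 3 target voxels at [30, 25, 20] Gy; 2 external voxels at 25 Gy
        vals = np.zeros((5, 5, 1))
        target = np.zeros((5, 5, 1), bool)
        target[0, 0] = target[0, 1] = target[0, 2] = True
        vals[0, 0] = 30.0
        vals[0, 1] = 25.0
        vals[0, 2] = 20.0
        vals[2, 0] = vals[2, 1] = 25.0
        dose = _grid(vals, spacing=1.0)
        q = plan_quality(dose, target, prescription=24.0)
        # TV=3, V_RI=4, TV_RI=2 -> nCI = 3*4/4 = 3; D5=30, D95=20 -> HI=1.5
        # V(>=12)=5 -> GI = 5/4
        assert q.nci == pytest.approx(3.0)
        assert q.hi == pytest.approx(1.5)
        assert q.gi == pytest.approx(1.25)

    def test_undefined_denominators_are_none(self):
        target = np.zeros((6, 6, 6), bool)
        target[2:4, 2:4, 2:4] = True
        dose = _grid(np.full((6, 6, 6), 1.0))
        q = plan_quality(dose, target, prescription=24.0)
        assert q.nci is None
        assert q.gi is None

    def test_gradient_index_spherical_profile(self):
        # linear radial falloff from 2 Rx at the center, zero at R=40 mm:
        # iso(Rx) at r=R/2, iso(Rx/2) at r=3R/4 -> GI = (3/4)^3/(1/2)^3
        n, rx, R = 88, 10.0, 40.0
        grid = VolumeGrid(np.zeros((n, n, n)), origin=-(np.array([n] * 3) - 1) / 2,
                          spacing=(1, 1, 1))
        r = np.linalg.norm(grid.voxel_centers(), axis=-1)
        dose = grid.with_values(np.maximum(2 * rx * (1 - r / R), 0.0))
        target = r <= 5.0
        q = plan_quality(dose, target, prescription=rx)
        assert q.gi == pytest.approx((3 / 4) ** 3 / (1 / 2) ** 3, rel=0.03)


class TestDoseDifferenceReport:
    def _structures(self, grid):
        ss = StructureSet(grid=grid)
        target = np.zeros(grid.shape, bool)
        target[3:6, 3:6, 3:6] = True
        oar = np.zeros(grid.shape, bool)
        oar[0:2, 0:2, 0:2] = True
        ss.add("PTV", target, StructureRole.TARGET_PTV)
        ss.add("Brainstem", oar, StructureRole.OAR)
        return ss

    def test_identity_gives_zero_deltas(self):
        rng = np.random.default_rng(7)
        ref = _grid(rng.uniform(0, 30, (9, 9, 9)))
        ss = self._structures(ref)
        table, diffvol = dose_difference_report(ref, ref, ss)
        num = table.select_dtypes("number")
        assert (num.fillna(0.0) == 0.0).all().all()
        assert diffvol.values.max() == 0.0

    def test_uniform_shift_propagates(self):
        rng = np.random.default_rng(8)
        ref = _grid(rng.uniform(0, 30, (9, 9, 9)))
        ev = ref.with_values(ref.values + 1.0)
        table, _ = dose_difference_report(ref, ev, self._structures(ref))
        assert np.allclose(table["delta_dmax_gy"], 1.0)
        assert np.allclose(table["delta_dmean_gy"], 1.0)

    def test_multiplicative_scaling_linearity(self):
        rng = np.random.default_rng(9)
        ref = _grid(rng.uniform(0, 30, (9, 9, 9)))
        ss = self._structures(ref)
        ev = ref.with_values(ref.values * 1.03)
        table, _ = dose_difference_report(ref, ev, ss)
        for _, row in table.iterrows():
            mask = ss.masks[row["structure"]]
            assert row["delta_dmean_gy"] == pytest.approx(
                0.03 * ref.values[mask].mean(), rel=1e-5
            )

    def test_empty_structure_skipped_with_warning(self):
        ref = _grid(np.ones((6, 6, 6)))
        ss = StructureSet(grid=ref)
        ss.add("PTV", np.ones(ref.shape, bool), StructureRole.TARGET_PTV)
        ss.add("Empty", np.zeros(ref.shape, bool), StructureRole.OAR)
        with pytest.warns(UserWarning, match="Empty"):
            table, _ = dose_difference_report(ref, ref, ss)
        assert list(table["structure"]) == ["PTV"]


class TestGammaMap:
    def test_gamma_map_consistent_with_pass_mask(self):
        from cyberbeam.metrics import gamma_map
        rng = np.random.default_rng(11)
        ref = _grid(_smooth_field(rng, (10, 10, 10)))
        ev = ref.with_values(ref.values + rng.normal(0, 0.3, ref.shape))
        mask = np.ones(ref.shape, bool)
        crit = GammaCriteria(3, 2)
        gm = gamma_map(ref, ev, mask, crit, subdivisions=2)
        passed, inc = gamma_pass_mask(ref, ev, mask, crit, subdivisions=2)
        assert np.all(np.isfinite(gm[inc]))
        assert np.array_equal(gm[inc] <= 1.0, passed[inc])
        # identity: gamma is exactly zero everywhere
        gm0 = gamma_map(ref, ref, mask, crit)
        assert np.all(gm0[inc] == 0.0)
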