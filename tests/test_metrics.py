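"""Plan evaluation tests: DVH, conformity, integral dose, PDD, gamma,
sensitivity."""
import numpy as np
import pytest

from speleoplan.engine import DepthDoseCurve
from speleoplan.grids import DoseGrid
from speleoplan.metrics import (conformity, dmax_1cc, dose_at_volume, dvh,
                                extract_pdd, gamma_index, integral_dose,
                                plateau_uniformity, sensitivity_study)


def _grid(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    return DoseGrid(values, np.zeros(3), np.asarray(spacing))


class TestDVH:
    def test_uniform_dose_is_step_function(self):
        d = _grid(np.full((4, 4, 4), 3.0))
        mask = np.ones((4, 4, 4), bool)
        h = dvh(d, mask, bin_width=0.5)
        assert h.v_at(0.0) == 1.0
        assert h.v_at(2.9) == 1.0
        assert h.v_at(3.5) == 0.0

    def test_volume_at_zero_always_one(self, rng):
        d = _grid(rng.uniform(0, 10, (5, 5, 5)))
        h = dvh(d, np.ones((5, 5, 5), bool))
        assert h.volume_fraction[0] == 1.0
        assert np.all(np.diff(h.volume_fraction) <= 0)

    def test_d95_matches_sorting_oracle(self, rng):
        vals = rng.uniform(0, 60, (8, 8, 8))
        d = _grid(vals)
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        d95 = dose_at_volume(d, mask, 95.0)
        expect = np.percentile(vals[mask], 5.0)
        assert d95 == pytest.approx(expect)

    def test_empty_mask_rejected(self):
        d = _grid(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            dvh(d, np.zeros((3, 3, 3), bool))


class TestConformity:
    def test_exact_target_dose_gives_unit_ci(self):
        vals = np.zeros((6, 6, 6))
        target = np.zeros((6, 6, 6), bool)
        target[2:4, 2:4, 2:4] = True
        vals[target] = 50.0
        r = conformity(_grid(vals), target, 0.9, 50.0)
        assert r["ci"] == pytest.approx(1.0)
        assert r["encapsulation"] == pytest.approx(1.0)

    def test_dilated_isodose_matches_volume_ratio(self):
        from scipy.ndimage import binary_dilation
        target = np.zeros((20, 20, 20), bool)
        target[5:15, 5:15, 5:15] = True
        iso = binary_dilation(target, iterations=2)
        vals = np.where(iso, 50.0, 0.0)
        r = conformity(_grid(vals), target, 0.9, 50.0)
        assert r["ci"] == pytest.approx(iso.sum() / target.sum())

    def test_ci50_at_least_ci90(self, rng):
        vals = rng.uniform(0, 60, (10, 10, 10))
        target = np.zeros((10, 10, 10), bool)
        target[3:7, 3:7, 3:7] = True
        d = _grid(vals)
        assert conformity(d, target, 0.5, 50.0)["ci"] >= \
            conformity(d, target, 0.9, 50.0)["ci"]

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            conformity(_grid(np.ones((3, 3, 3))),
                       np.zeros((3, 3, 3), bool), 0.9, 50.0)


class TestIntegralDose:
    def test_unit_conversion(self):
        # 1 Gy uniform over 1000 cm^3 -> 1.0 unit of 1e-3 Gy m^3
        vals = np.ones((10, 10, 10))
        d = DoseGrid(vals, np.zeros(3), np.array([10.0, 10.0, 10.0]))
        body = np.ones((10, 10, 10), bool)
        assert integral_dose(d, body) == pytest.approx(1.0)

    def test_linear_in_dose(self, rng):
        vals = rng.uniform(0, 5, (6, 6, 6))
        d1 = _grid(vals)
        d2 = _grid(2 * vals)
        body = np.ones((6, 6, 6), bool)
        assert integral_dose(d2, body) == pytest.approx(
            2 * integral_dose(d1, body))

    def test_matches_direct_summation(self, rng):
        vals = rng.uniform(0, 5, (6, 6, 6))
        d = DoseGrid(vals, np.zeros(3), np.array([2.0, 3.0, 1.5]))
        body = rng.uniform(0, 1, (6, 6, 6)) > 0.4
        expect = float(vals[body].sum()) * 9.0 / 1e6
        assert integral_dose(d, body) == pytest.approx(expect, rel=1e-12)


class TestDmax1cc:
    def test_hottest_cubic_centimetre(self):
        vals = np.zeros((10, 10, 10))
        vals[0, 0, :] = np.arange(10.0)
        # voxel volume 125 mm^3 -> 1 cc = 8 voxels
        d = DoseGrid(vals, np.zeros(3), np.array([5.0, 5.0, 5.0]))
        assert dmax_1cc(d, np.ones((10, 10, 10), bool)) == 2.0


class TestExtractPdd:
    def test_normalisation_point_is_100(self, small_water_box, beam150):
        from speleoplan.engine import Beamlet, field_dose
        dose = field_dose([Beamlet(0, 0, 150.0, 0)], small_water_box,
                          None, beam150)
        pdd = extract_pdd(dose, small_water_box, normalization_depth=40.0)
        assert pdd.at(np.array([40.0]))[0] == pytest.approx(100.0, rel=1e-6)

    def test_reference_depth_outside_grid_rejected(self, small_water_box,
                                                   beam150):
        from speleoplan.engine import Beamlet, field_dose
        dose = field_dose([Beamlet(0, 0, 150.0, 0)], small_water_box,
                          None, beam150)
        with pytest.raises(ValueError):
            extract_pdd(dose, small_water_box, normalization_depth=500.0)

    def test_plateau_uniformity_formula(self):
        depths = np.arange(0.0, 10.0, 0.5)
        dose = np.full_like(depths, 100.0)
        dose[4] = 104.0
        c = DepthDoseCurve(depths, dose)
        u = plateau_uniformity(c, (0.0, 9.5))
        mean = dose.mean()
        assert u["max_deviation_pct"] == pytest.approx(
            100 * (104.0 - mean) / mean)


class TestGammaIndex:
    def test_identical_distributions_pass_everywhere(self):
        depths = np.arange(0.0, 50.0, 0.5)
        dose = np.exp(-(depths - 25.0) ** 2 / 30.0)
        c = DepthDoseCurve(depths, dose)
        r = gamma_index(c, c, 1.0, 1.0)
        assert r["pass_fraction"] == 1.0
        assert np.allclose(r["gamma"], 0.0, atol=1e-3)

    def test_uniform_one_percent_offset_is_boundary(self):
        """+1% of the global max everywhere at 1%/1 mm sits exactly on
        the gamma = 1 boundary."""
        depths = np.arange(0.0, 30.0, 0.5)
        ref = np.full_like(depths, 1.0)
        ev = ref + 0.01
        r = gamma_index((ev, [0.5]), (ref, [0.5]), 1.0, 1.0)
        assert np.allclose(r["gamma"], 1.0, atol=1e-6)
        assert r["pass_fraction"] == 1.0

    def test_small_shift_matches_brute_force(self):
        """A 0.5 mm rigid shift of a steep profile: gamma equals an
        exhaustive fine-grid minimisation."""
        depths = np.arange(0.0, 40.0, 0.5)
        prof = 1.0 / (1.0 + np.exp((depths - 20.0) / 1.5))
        ref = DepthDoseCurve(depths, prof)
        ev = DepthDoseCurve(depths, np.interp(depths - 0.5, depths, prof))
        r = gamma_index(ev, ref, 1.0, 1.0)
        # brute force on a 0.01 mm grid
        fine = np.arange(0.0, 40.0, 0.01)
        rf = np.interp(fine, depths, prof)
        dose_tol = 0.01 * prof.max()
        gamma_bf = np.empty_like(depths)
        for i, (d0, v0) in enumerate(zip(depths, ev.dose)):
            m = np.abs(fine - d0) <= 3.0
            g2 = (fine[m] - d0) ** 2 / 1.0 + (rf[m] - v0) ** 2 / dose_tol ** 2
            gamma_bf[i] = np.sqrt(g2.min())
        assert np.abs(r["gamma"] - gamma_bf).max() < 2e-2
        assert abs(r["pass_fraction"]
                   - float(np.mean(gamma_bf <= 1.0))) < 0.05

    def test_zero_reference_rejected(self):
        depths = np.arange(0.0, 10.0, 0.5)
        z = DepthDoseCurve(depths, np.zeros_like(depths))
        with pytest.raises(ValueError):
            gamma_index(z, z, 1.0, 1.0)


class TestSensitivityStudy:
    @pytest.fixture(scope="class")
    def toy_plan(self):
        from speleoplan.engine import Beamlet, field_dose
        from speleoplan.phantoms import make_ground_truth_case
        case = make_ground_truth_case(seed=9)
        spots = [Beamlet(s.bev_x, s.bev_y, s.energy, s.gantry_angle, w)
                 for s, w in zip(case.spots, case.weights_truth)]
        base = field_dose(spots, case.phantom, case.filter_truth, case.beam)
        rx = float(np.percentile(
            base.values[case.phantom.roi_masks["target"]], 5))
        return case, spots, rx

    def test_zero_delta_reports_zero_changes(self, toy_plan):
        case, spots, rx = toy_plan
        r = sensitivity_study(spots, case.filter_truth, case.phantom,
                              case.beam, rx, deltas=())
        z = r["deltas"][0.0]
        assert z["d_v_rx"] == 0.0 and z["d_falloff80_mm"] == 0.0

    def test_coverage_non_increasing_with_taller_pillars(self, toy_plan):
        """Uniformly taller pillars pull the dose upstream and can only
        reduce prescription coverage."""
        case, spots, rx = toy_plan
        r = sensitivity_study(spots, case.filter_truth, case.phantom,
                              case.beam, rx, deltas=(0.5, 1.0))
        assert r["deltas"][0.5]["d_v_rx"] <= 1e-12
        assert r["deltas"][1.0]["d_v_rx"] <= r["deltas"][0.5]["d_v_rx"] \
            + 1e-12

    def test_distal_falloff_shifts_by_wet(self, toy_plan):
        """The distal 80% edge moves upstream by delta x rsp."""
        case, spots, rx = toy_plan
        r = sensitivity_study(spots, case.filter_truth, case.phantom,
                              case.beam, rx, deltas=(1.0, -1.0))
        vz = case.phantom.spacing[2]
        rsp = case.filter_truth.material.rsp
        assert abs(r["deltas"][1.0]["d_falloff80_mm"] + rsp) <= vz + 0.1
        assert abs(r["deltas"][-1.0]["d_falloff80_mm"] - rsp) <= vz + 0.1

    def test_clamping_flagged(self, toy_plan):
        case, spots, rx = toy_plan
        low = case.filter_truth.with_heights(
            np.clip(case.filter_truth.heights, 0.0, 0.4))
        r = sensitivity_study(spots, low, case.phantom, case.beam, rx,
                              deltas=(-1.0,))
        assert r["deltas"][-1.0]["clamped"]
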