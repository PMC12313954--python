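"""Arc/IMPT planner tests: spot placement, energy segmentation, dose
influence, NNLS weights, energy-change accounting."""
import numpy as np
import pytest

from speleoplan.arc import (ArcLayout, Beamlet, DoseInfluence, Plan,
                            assign_segment_energies, build_dose_influence,
                            count_energy_changes, optimize_weights,
                            place_spots_arc, place_spots_impt,
                            segment_energies, target_depth_interval)
from speleoplan.engine import BeamModel, field_dose
from speleoplan.filters import SpeleoFilter
from speleoplan.phantoms import PhantomSpec, make_phantom
from scipy import sparse


@pytest.fixture(scope="module")
def slab_phantom():
    return make_phantom(PhantomSpec(voxel_size=(2.5, 5.0, 2.5),
                                    slab_2d=True))


@pytest.fixture(scope="module")
def offset_phantom():
    return make_phantom(PhantomSpec(target_offset_mm=50.0,
                                    voxel_size=(2.5, 5.0, 2.5),
                                    slab_2d=True))


@pytest.fixture(scope="module")
def beam():
    return BeamModel(nominal_energy=150.0)


@pytest.fixture(scope="module")
def sobp_filter_5cm():
    """Quick 5 cm SOBP filter (superposition model only) for
    segmentation tests."""
    from speleoplan.pipeline import design_sobp_filter
    from speleoplan.sobp import DesignerConfig
    out = design_sobp_filter(
        50.0, cfg=DesignerConfig(seed=1, goal_correction_rounds=0,
                                 iterations=8))
    return out.filter


class TestPlaceSpots:
    def test_bev_columns_count_closed_form(self, slab_phantom, beam):
        """Primary columns x rows x 5 secondary offsets."""
        layout = ArcLayout(span=(0.0, 360.0), angle_step=10.0)
        spots = place_spots_arc(slab_phantom, layout, beam,
                                primary_spacing=5.0, margin=5.0)
        # planar phantom: target BEV extent is its diameter + margins
        bx0, bx1 = -24.0, 24.0   # voxel-centre extent of the 50 mm target
        n_cols = len(np.arange(bx0 - 5.0, bx1 + 5.0 + 1e-9, 5.0))
        assert len(spots) == n_cols * 1 * 5

    def test_single_angle_gives_10mm_band(self, slab_phantom, beam):
        layout = ArcLayout(span=(0.0, 1.0), angle_step=1.0)
        spots = place_spots_arc(slab_phantom, layout, beam)
        assert all(s.gantry_angle == 0.0 for s in spots)
        for col in {round(s.bev_x, 6) for s in spots}:
            pass
        xs = sorted({s.bev_x for s in spots})
        # secondary offsets span +-5 mm around each primary column
        assert max(xs) - min(xs) >= 10.0

    def test_spots_within_field(self, slab_phantom, beam):
        layout = ArcLayout(span=(0.0, 360.0), angle_step=15.0)
        for s in place_spots_arc(slab_phantom, layout, beam):
            assert abs(s.bev_x) <= beam.field_size[0] / 2 + 1e-9
            assert abs(s.bev_y) <= beam.field_size[1] / 2 + 1e-9

    def test_full_surface_count(self, slab_phantom, beam):
        layout = ArcLayout(span=(0.0, 90.0), angle_step=30.0)
        spots = place_spots_arc(slab_phantom, layout, beam,
                                mode="full_surface")
        assert len(spots) == 3 * 21   # 3 angles x 21 columns at 2.5 mm


class TestSegmentEnergies:
    def test_central_target_single_segment(self, slab_phantom, beam,
                                           sobp_filter_5cm):
        layout = ArcLayout(span=(0.0, 360.0), angle_step=10.0)
        segs = segment_energies(slab_phantom, layout, sobp_filter_5cm,
                                beam, [150.0])
        assert len(segs) == 1

    def test_offset_target_three_stated_energies_three_segments(
            self, offset_phantom, beam, sobp_filter_5cm):
        """A quarter arc over the offset target partitions into three
        contiguous segments when given the three delivery energies."""
        layout = ArcLayout(span=(0.0, 90.0), angle_step=1.0)
        segs = segment_energies(offset_phantom, layout, sobp_filter_5cm,
                                beam, [119.1, 128.9, 136.9])
        assert len(segs) == 3
        assert [s.energy for s in segs] == [119.1, 128.9, 136.9]
        # contiguous and monotone boundaries
        for a, b in zip(segs, segs[1:]):
            assert a.angle_stop == b.angle_start

    def test_greedy_minimal_vs_exhaustive_oracle(self, offset_phantom,
                                                 beam, sobp_filter_5cm):
        """Greedy segment count equals the DP optimum over the same
        feasibility table."""
        from speleoplan.arc import (_coverage_violation,
                                    filter_sobp_interval)
        from speleoplan.engine import proton_range
        layout = ArcLayout(span=(0.0, 90.0), angle_step=5.0)
        grid = np.array([110.0, 119.1, 128.9, 136.9, 145.0])
        tol = 5.0
        p0, p1 = filter_sobp_interval(sobp_filter_5cm, 150.0, beam)
        shifts = proton_range(grid) - proton_range(150.0)
        angles = layout.angles
        feas = np.zeros((len(angles), len(grid)), bool)
        viol = np.zeros_like(feas, dtype=float)
        for a, ang in enumerate(angles):
            dp, dd = target_depth_interval(offset_phantom, float(ang))
            for e in range(len(grid)):
                viol[a, e] = _coverage_violation(p0 + shifts[e],
                                                 p1 + shifts[e], dp, dd)
            feas[a] = viol[a] <= tol
        if not feas.all(axis=1).any() and (~feas.any(axis=1)).any():
            tol = max(tol, float(viol.min(axis=1).max()) + 1e-9)
            feas = viol <= tol
        # DP oracle: minimal number of contiguous single-energy runs
        INF = 10 ** 9
        best = [0] + [INF] * len(angles)
        for i in range(1, len(angles) + 1):
            cur = np.ones(len(grid), bool)
            for j in range(i, 0, -1):
                cur &= feas[j - 1]
                if not cur.any():
                    break
                best[i] = min(best[i], best[j - 1] + 1)
        segs = segment_energies(offset_phantom, layout, sobp_filter_5cm,
                                beam, grid, coverage_tol_mm=tol)
        assert len(segs) == best[len(angles)]

    def test_strict_mode_names_uncovered_angle(self, offset_phantom, beam,
                                               sobp_filter_5cm):
        layout = ArcLayout(span=(0.0, 90.0), angle_step=5.0)
        with pytest.raises(ValueError, match="deg"):
            segment_energies(offset_phantom, layout, sobp_filter_5cm,
                             beam, [80.0], coverage_tol_mm=2.0,
                             strict=True)


class TestCountEnergyChanges:
    def test_four_field_impt_on_stated_grid(self, slab_phantom, beam):
        """Four fields, 21 layers each on the 2.5 MeV grid from 100 to
        150 MeV: 80 energy changes."""
        layout = ArcLayout(span=(0.0, 360.0), mode="fixed_fields",
                           field_angles=(0.0, 90.0, 180.0, 270.0))
        spots = place_spots_impt(slab_phantom, layout.field_angles, beam,
                                 energies=np.arange(100.0, 150.0 + 1e-9,
                                                    2.5))
        assert count_energy_changes(Plan(spots, layout)) == 80

    def test_single_energy_full_arc_zero_changes(self):
        layout = ArcLayout(span=(0.0, 360.0), angle_step=1.0)
        from speleoplan.arc import EnergySegment
        seg = [EnergySegment(0.0, 360.0, 150.0)]
        plan = Plan([Beamlet(0, 0, 150.0, 10.0)], layout, seg)
        assert count_energy_changes(plan) == 0

    def test_three_segment_quarter_arc_two_changes(self):
        from speleoplan.arc import EnergySegment
        layout = ArcLayout(span=(0.0, 90.0), angle_step=1.0)
        segs = [EnergySegment(0.0, 53.0, 119.1),
                EnergySegment(53.0, 74.0, 128.9),
                EnergySegment(74.0, 90.0, 136.9)]
        spots = [Beamlet(0, 0, s.energy, (s.angle_start + s.angle_stop) / 2)
                 for s in segs]
        assert count_energy_changes(Plan(spots, layout, segs)) == 2

    def test_empty_plan_rejected(self):
        layout = ArcLayout(span=(0.0, 90.0))
        with pytest.raises(ValueError):
            count_energy_changes(Plan([], layout))


class TestDoseInfluence:
    def test_matrix_times_ones_matches_field_dose(self, slab_phantom, beam):
        spots = [Beamlet(x, 0.0, 150.0, 0.0) for x in (-5.0, 0.0, 5.0)]
        di = build_dose_influence(spots, slab_phantom, None, beam)
        ref = field_dose(spots, slab_phantom, None, beam)
        got = di.dose_grid(np.ones(3), slab_phantom.origin,
                           slab_phantom.spacing)
        body = slab_phantom.roi_masks["body"]
        err = np.abs(got.values - ref.values)[body]
        assert err.max() <= 2e-3 * ref.values.max()   # sparsity cutoff

    def test_symmetric_spots_give_mirror_columns(self, slab_phantom, beam):
        spots = [Beamlet(-10.0, 0.0, 150.0, 0.0),
                 Beamlet(10.0, 0.0, 150.0, 0.0)]
        di = build_dose_influence(spots, slab_phantom, None, beam)
        a = di.dose_grid(np.array([1.0, 0.0]), slab_phantom.origin,
                         slab_phantom.spacing).values
        b = di.dose_grid(np.array([0.0, 1.0]), slab_phantom.origin,
                         slab_phantom.spacing).values
        np.testing.assert_allclose(a, b[::-1, :, :], rtol=0.01,
                                   atol=1e-3 * a.max())

    def test_entries_nonnegative(self, slab_phantom, beam):
        spots = [Beamlet(0.0, 0.0, 150.0, 45.0)]
        di = build_dose_influence(spots, slab_phantom, None, beam)
        assert di.matrix.min() >= 0.0


class TestOptimizeWeights:
    def _make_di(self, D, masks_shape=(None)):
        n_vox, n_spots = D.shape
        vidx = np.arange(n_vox)
        return DoseInfluence(sparse.csr_matrix(D), vidx,
                             (n_vox, 1, 1), [], 1.0)

    def test_identity_matrix_reproduces_goal(self):
        D = np.eye(4)
        di = self._make_di(D)
        masks = {"target": np.ones((4, 1, 1), bool)}
        res = optimize_weights(di, {"target": {"type": "uniform",
                                               "dose": 2.0}},
                               masks, renormalize_d95=False)
        np.testing.assert_allclose(res.weights, 2.0, rtol=1e-4)

    def test_two_spot_closed_form_nnls(self):
        """2x2 system with known normal-equation solution, cross-checked
        against the reference active-set NNLS."""
        from scipy.optimize import nnls as scipy_nnls
        D = np.array([[1.0, 0.5], [0.5, 1.0]])
        di = self._make_di(D)
        masks = {"target": np.ones((2, 1, 1), bool)}
        res = optimize_weights(di, {"target": {"type": "uniform",
                                               "dose": 1.0}},
                               masks, renormalize_d95=False)
        x_closed = np.linalg.solve(D, np.ones(2))     # interior solution
        x_ref, _ = scipy_nnls(D, np.ones(2))
        np.testing.assert_allclose(x_closed, x_ref, atol=1e-12)
        np.testing.assert_allclose(res.weights, x_closed, atol=1e-3)

    def test_active_constraint_case(self):
        """A system whose unconstrained optimum is negative: the NNLS
        solution clamps that weight at zero (active-set oracle)."""
        from scipy.optimize import nnls as scipy_nnls
        D = np.array([[1.0, 0.95], [0.95, 1.0], [1.0, 0.2]])
        d = np.array([1.0, 0.2, 1.0])
        x_ref, _ = scipy_nnls(D, d)
        assert x_ref.min() == 0.0
        di = self._make_di(D)
        masks = {"target": np.ones((3, 1, 1), bool)}
        res = optimize_weights(di, {"target": {"type": "match",
                                               "dose": d.reshape(3, 1, 1)}},
                               masks, renormalize_d95=False, max_iter=5000)
        np.testing.assert_allclose(res.weights, x_ref, atol=2e-3)

    def test_weights_always_nonnegative(self, rng):
        D = rng.uniform(0, 1, (20, 8))
        di = self._make_di(D)
        masks = {"target": np.ones((20, 1, 1), bool)}
        res = optimize_weights(di, {"target": {"type": "uniform",
                                               "dose": 1.0}},
                               masks, renormalize_d95=False)
        assert np.all(res.weights >= 0)

    def test_objective_trace_monotone(self):
        D = np.array([[1.0, 0.5], [0.5, 1.0]])
        di = self._make_di(D)
        masks = {"target": np.ones((2, 1, 1), bool)}
        res = optimize_weights(di, {"target": {"type": "uniform",
                                               "dose": 1.0}},
                               masks, renormalize_d95=False)
        t = np.asarray(res.objective_trace)
        assert np.all(np.diff(t) <= 1e-15)

    def test_prescription_scaling_homogeneity(self):
        """Scaling the prescription scales the optimal weights."""
        D = np.array([[1.0, 0.3], [0.3, 1.0], [0.6, 0.6]])
        di = self._make_di(D)
        masks = {"target": np.ones((3, 1, 1), bool)}
        r1 = optimize_weights(di, {"target": {"type": "uniform",
                                              "dose": 1.0}},
                              masks, renormalize_d95=False)
        r2 = optimize_weights(di, {"target": {"type": "uniform",
                                              "dose": 3.0}},
                              masks, renormalize_d95=False)
        np.testing.assert_allclose(r2.weights, 3.0 * r1.weights, rtol=1e-3)

    def test_d95_renormalization(self):
        D = np.eye(5)
        di = self._make_di(D)
        masks = {"target": np.ones((5, 1, 1), bool)}
        res = optimize_weights(di, {"target": {"type": "uniform",
                                               "dose": 50.0}}, masks)
        dose = D @ res.weights
        assert np.percentile(dose, 5) == pytest.approx(50.0, rel=1e-6)


class TestPlanValidation:
    def test_spot_energy_must_match_segment(self):
        from speleoplan.arc import EnergySegment
        layout = ArcLayout(span=(0.0, 90.0))
        segs = [EnergySegment(0.0, 90.0, 120.0)]
        with pytest.raises(ValueError):
            Plan([Beamlet(0, 0, 150.0, 45.0)], layout, segs)

    def test_assign_segment_energies(self):
        from speleoplan.arc import EnergySegment
        segs = [EnergySegment(0.0, 45.0, 120.0),
                EnergySegment(45.0, 90.0, 130.0)]
        spots = [Beamlet(0, 0, 150.0, 10.0), Beamlet(0, 0, 150.0, 80.0)]
        out = assign_segment_energies(spots, segs)
        assert [s.energy for s in out] == [120.0, 130.0]
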