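"""Bead-constellation registration, error budgets, and rigid point-to-curve
correlation with cross-validation and z alignment."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from cryopalm.geometry import point_to_polyline_distance
from cryopalm.registration import (CorrelationResult, RegistrationErrorBudget,
                                   align_z, combine_errors,
                                   crossvalidate_registration,
                                   filter_by_precision, register_point_sets,
                                   register_points_to_curve)
from cryopalm.synthetic import simulate_membrane_scene
from cryopalm.transforms import RigidTransform2D

TRUTH = RigidTransform2D(20.0, -10.0, np.radians(2.0), pivot=(0.0, 0.0))


class TestPointSetRegistration:
    def test_identical_sets_give_identity_and_zero_error(self, rng):
        pts = rng.uniform(0, 5000, (8, 2))
        tform, eps = register_point_sets(pts, pts)
        assert eps == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tform(pts), pts, atol=1e-9)

    def test_known_similarity_with_jitter(self, rng):
        src = rng.uniform(0, 5000, (10, 2))
        c, s = np.cos(0.1), np.sin(0.1)
        dst = 1.02 * src @ np.array([[c, -s], [s, c]]).T + [120.0, -60.0]
        dst = dst + rng.normal(0, 2.0, dst.shape)
        tform, eps = register_point_sets(src, dst)
        assert eps == pytest.approx(2.0, abs=1.2)          # ~ the injected jitter
        assert tform.scale == pytest.approx(1.02, abs=0.01)
        assert tform.rotation == pytest.approx(0.1, abs=0.01)

    def test_collinear_beads_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="collinear"):
            register_point_sets(src, src)

    def test_too_few_correspondences(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            register_point_sets(pts, pts, model="similarity")


class TestErrorBudget:
    def test_zero_components(self):
        assert combine_errors([0.0, 0.0, 0.0]) == 0.0

    def test_pythagorean_quadruple(self):
        assert combine_errors([3.0, 4.0, 12.0]) == pytest.approx(13.0)

    def test_total_at_least_max_component(self, rng):
        comps = rng.uniform(0, 10, 3)
        budget = RegistrationErrorBudget(*comps)
        assert budget.total_nm >= comps.max()

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            combine_errors([-1.0, 2.0, 3.0])


class TestCurveRegistration:
    def test_unperturbed_points_give_identity(self):
        tbl, curve = simulate_membrane_scene(400.0, 100, 0.0, seed=5)
        res = register_points_to_curve(tbl, curve)
        assert abs(res.transform.dx) < 0.5
        assert abs(res.transform.dy) < 0.5
        assert abs(np.degrees(res.transform.theta)) < 0.05
        assert res.sum_distance_nm < 1.0 * len(tbl)

    def test_known_perturbation_recovered(self):
        tbl, curve = simulate_membrane_scene(400.0, 300, 5.0, transform=TRUTH,
                                             seed=3)
        res = register_points_to_curve(tbl, curve)
        fit = res.transform.about_pivot((0.0, 0.0))
        assert fit.dx == pytest.approx(20.0, abs=2.0)
        assert fit.dy == pytest.approx(-10.0, abs=2.0)
        assert np.degrees(fit.theta) == pytest.approx(2.0, abs=0.2)

    def test_objective_at_optimum_beats_truth(self):
        tbl, curve = simulate_membrane_scene(400.0, 200, 0.0, transform=TRUTH,
                                             seed=9)
        res = register_points_to_curve(tbl, curve)
        pts = tbl[["x_nm", "y_nm"]].to_numpy()
        at_truth = point_to_polyline_distance(TRUTH.apply(pts), curve).sum()
        assert res.sum_distance_nm <= at_truth + 1e-6

    def test_far_outliers_do_not_shift_optimum(self, rng):
        tbl, curve = simulate_membrane_scene(400.0, 300, 5.0, transform=TRUTH,
                                             seed=3)
        clean = register_points_to_curve(tbl, curve)
        dirty = tbl.copy()
        idx = rng.choice(len(dirty), 30, replace=False)
        ang = rng.uniform(0, 2 * np.pi, 30)
        dirty.loc[dirty.index[idx], "x_nm"] += 400 * np.cos(ang)
        dirty.loc[dirty.index[idx], "y_nm"] += 400 * np.sin(ang)
        res = register_points_to_curve(dirty, curve)
        a, b = res.transform.about_pivot((0, 0)), clean.transform.about_pivot((0, 0))
        assert abs(a.dx - b.dx) < 2.0
        assert abs(a.dy - b.dy) < 2.0
        assert abs(np.degrees(a.theta - b.theta)) < 0.2
        assert res.n_excluded >= 20

    def test_enlarging_exclusion_never_drops_included(self):
        tbl, curve = simulate_membrane_scene(400.0, 150, 10.0, seed=7)
        n_incl = [register_points_to_curve(tbl, curve, exclusion_nm=e).included.sum()
                  for e in [30.0, 60.0, 120.0, 240.0]]
        assert all(a <= b for a, b in zip(n_incl, n_incl[1:]))

    def test_too_few_reachable_molecules_raises(self):
        tbl = make_table(np.full(5, 1e6), 1e6)
        _, curve = simulate_membrane_scene(400.0, 10, 0.0, seed=0)
        with pytest.raises(ValueError):
            register_points_to_curve(tbl, curve)


class TestCrossValidation:
    def test_on_curve_molecules_have_zero_holdout_distance(self):
        tbl, curve = simulate_membrane_scene(400.0, 120, 0.0, seed=2)
        cv = crossvalidate_registration(tbl, curve, seed=0)
        assert cv["mean_nm"] < 1.0
        assert cv["n_train"] == len(tbl) - cv["n_holdout"]

    def test_label_offset_fixture_reads_back(self):
        tbl, curve = simulate_membrane_scene(400.0, 300, 3.0,
                                             radial_offset_nm=8.6, seed=11)
        cv = crossvalidate_registration(tbl, curve, seed=1)
        assert cv["mean_nm"] == pytest.approx(8.6, abs=1.0)

    def test_seed_stability(self):
        tbl, curve = simulate_membrane_scene(400.0, 300, 3.0,
                                             radial_offset_nm=8.6, seed=11)
        m1 = crossvalidate_registration(tbl, curve, seed=1)["mean_nm"]
        m2 = crossvalidate_registration(tbl, curve, seed=2)["mean_nm"]
        assert abs(m1 - m2) < 1.0

    def test_needs_thirty_molecules(self):
        tbl, curve = simulate_membrane_scene(400.0, 20, 0.0, seed=0)
        with pytest.raises(ValueError):
            crossvalidate_registration(tbl, curve, seed=0)


class TestAlignZ:
    def test_240nm_distribution_consistent_with_220nm_tomogram(self, rng):
        z = rng.normal(0, 101.9, 5000)           # FWHM 240 nm
        out = align_z(z, tomogram_thickness_nm=220.0)
        assert out["consistent"]
        assert out["thickness_nm"] == pytest.approx(240.0, abs=6.0)

    def test_constant_z_degenerate(self):
        out = align_z(np.full(200, 5.0), 220.0)
        assert out["degenerate"]

    def test_shifted_peak_recovered(self, rng):
        z = rng.normal(50.0, 80.0, 5000)
        out = align_z(z, 220.0)
        assert out["z_offset_nm"] == pytest.approx(50.0, abs=3.0)

    def test_needs_enough_values(self):
        with pytest.raises(ValueError):
            align_z(np.zeros(10), 200.0)


class TestFilterByPrecision:
    def test_keep_all_is_identity(self, rng):
        tbl = make_table(rng.uniform(0, 100, 40), 0.0,
                         precision=rng.uniform(2, 20, 40))
        kept, summary = filter_by_precision(tbl, keep_fraction=1.0)
        assert len(kept) == 40 and summary["n_kept"] == 40

    def test_keep_fraction_order_statistics(self, rng):
        prec = rng.uniform(2, 20, 100)
        tbl = make_table(rng.uniform(0, 100, 100), 0.0, precision=prec)
        kept, _ = filter_by_precision(tbl, keep_fraction=0.1)
        assert len(kept) == 10
        dropped = tbl.drop(kept.index)
        assert kept.precision_nm.max() <= dropped.precision_nm.min()

    def test_reported_summary_matches_direct_computation(self, rng):
        """Keeping the best 10% reproduces the mean/median computed directly
        from the generator's draw."""
        prec = rng.lognormal(np.log(9.0), 0.6, 1000)
        tbl = make_table(rng.uniform(0, 100, 1000), 0.0, precision=prec)
        kept, summary = filter_by_precision(tbl, keep_fraction=0.1)
        direct = np.sort(prec)[:100]
        assert summary["precision_mean_nm"] == pytest.approx(direct.mean())
        assert summary["precision_median_nm"] == pytest.approx(np.median(direct))

    def test_exactly_one_selector_required(self):
        tbl = make_table([0.0], 0.0)
        with pytest.raises(ValueError):
            filter_by_precision(tbl)
        with pytest.raises(ValueError):
            filter_by_precision(tbl, keep_fraction=0.5, cutoff_nm=5.0)
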