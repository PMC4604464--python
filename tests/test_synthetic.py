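"""Synthetic-scene generators: photon accounting, determinism, geometry,
decay traces."""
import numpy as np
import pandas as pd
import pytest

from cryopalm.geometry import point_to_polyline_distance
from cryopalm.synthetic import (DecayTraceSpec, DriftModel, MovieTruthSpec,
                                SceneConfig, simulate_decay,
                                simulate_membrane_scene, simulate_movie,
                                simulate_multiring_scene,
                                simulate_switching_trace)
from cryopalm.transforms import RigidTransform2D


class TestSimulateMovie:
    def test_empty_scene_is_all_zero(self):
        cfg = SceneConfig(field_size_px=16, n_frames=3, background_ppp=0,
                          read_noise=0, shot_noise=False, seed=0)
        spec = MovieTruthSpec(geometry="uniform", n_emitters=0, n_beads=0)
        stack, truth = simulate_movie(cfg, spec)
        assert stack.sum() == 0
        assert truth.drift_nm.shape == (3, 3)

    def test_photon_conservation_single_emitter(self):
        """Noiseless stack integrates to the drawn budget (edge truncation
        plus integer rounding below 0.5%)."""
        cfg = SceneConfig(field_size_px=16, n_frames=5, background_ppp=0,
                          read_noise=0, shot_noise=False, gain=2.0, seed=1)
        spec = MovieTruthSpec(geometry="uniform", n_emitters=1, always_on=True,
                              fixed_photons=10000, fixed_z_nm=0.0, n_beads=0,
                              label_jitter_nm=0)
        stack, _ = simulate_movie(cfg, spec)
        assert stack.sum() / cfg.gain == pytest.approx(10000, rel=5e-3)

    def test_seed_determinism(self):
        cfg = SceneConfig(field_size_px=16, n_frames=10, seed=42)
        spec = MovieTruthSpec(geometry="ring", radius_nm=400, n_emitters=10,
                              center_nm=(1280.0, 1280.0))
        a, _ = simulate_movie(cfg, spec)
        b, _ = simulate_movie(cfg, spec)
        assert np.array_equal(a, b)

    def test_truth_invariants(self):
        cfg = SceneConfig(field_size_px=32, n_frames=50, seed=3)
        spec = MovieTruthSpec(geometry="ring", radius_nm=400, n_emitters=40,
                              label_jitter_nm=4.0)
        _, truth = simulate_movie(cfg, spec)
        half_t = truth.section_thickness_nm / 2
        assert np.all(np.abs(truth.emitter_xyz_nm[:, 2]) <= half_t)
        assert len(truth.drift_nm) == cfg.n_frames
        d = point_to_polyline_distance(truth.emitter_xyz_nm[:, :2], truth.membrane)
        assert np.all(d <= 5 * spec.label_jitter_nm)

    def test_geometry_outside_field_rejected(self):
        cfg = SceneConfig(field_size_px=16, n_frames=2)
        spec = MovieTruthSpec(geometry="ring", radius_nm=5000.0)
        with pytest.raises(ValueError, match="fit inside"):
            simulate_movie(cfg, spec)

    def test_negative_photon_budget_rejected(self):
        cfg = SceneConfig(field_size_px=16, n_frames=2)
        spec = MovieTruthSpec(geometry="uniform", n_emitters=2,
                              fixed_photons=-100.0)
        with pytest.raises(ValueError, match="positive"):
            simulate_movie(cfg, spec)

    def test_beads_present_in_every_frame(self):
        cfg = SceneConfig(field_size_px=16, n_frames=4, background_ppp=0,
                          read_noise=0, shot_noise=False, seed=0)
        spec = MovieTruthSpec(geometry="uniform", n_emitters=0, n_beads=2)
        stack, truth = simulate_movie(cfg, spec)
        assert len(truth.bead_xyz_nm) == 2
        assert np.all(stack.reshape(4, -1).sum(axis=1) > 0)


class TestMembraneScene:
    def test_zero_jitter_points_lie_on_curve(self):
        tbl, curve = simulate_membrane_scene(400.0, 50, 0.0, seed=0)
        d = point_to_polyline_distance(tbl[["x_nm", "y_nm"]].to_numpy(), curve)
        assert np.all(d < 2.0)   # below the curve sampling resolution

    def test_forward_transform_restores_on_curve_distances(self):
        t = RigidTransform2D(20.0, -10.0, np.radians(2.0))
        tbl, curve = simulate_membrane_scene(400.0, 60, 0.0, transform=t, seed=1)
        pts = tbl[["x_nm", "y_nm"]].to_numpy()
        # off the curve in the light frame, back on it after the forward map
        assert point_to_polyline_distance(t.apply(pts), curve).max() < 2.0

    def test_radial_offset_sets_mean_distance(self):
        """An 8.6 nm outward label displacement reads back as an 8.6 nm mean
        point-to-membrane distance."""
        tbl, curve = simulate_membrane_scene(400.0, 400, 0.0,
                                             radial_offset_nm=8.6, seed=2)
        d = point_to_polyline_distance(tbl[["x_nm", "y_nm"]].to_numpy(), curve)
        assert d.mean() == pytest.approx(8.6, abs=0.4)

    def test_too_few_emitters_rejected(self):
        with pytest.raises(ValueError):
            simulate_membrane_scene(400.0, 2, 0.0)

    def test_multiring_density_matches_request(self):
        tbl, contours, area = simulate_multiring_scene(density_per_um2=749.0, seed=0)
        assert len(tbl) / area == pytest.approx(749.0, rel=0.01)
        assert len(contours) >= 2


class TestDecayTraces:
    def test_single_exponential_closed_form(self):
        spec = DecayTraceSpec(A1=2.0, tau1_s=0.5, dt_s=0.001)
        tr = simulate_decay(spec, 2.0)
        at_tau = tr.intensity[np.isclose(tr.t_s, 0.5)].iloc[0]
        assert at_tau == pytest.approx(2.0 / np.e, rel=1e-3)

    def test_room_temperature_initial_value(self):
        # fast 0.06 s / 0.87 and slow 2.37 s / 0.04 sum to 0.91 at t = 0
        spec = DecayTraceSpec(A1=0.87, tau1_s=0.06, A2=0.04, tau2_s=2.37,
                              baseline=0.09, dt_s=0.01)
        tr = simulate_decay(spec, 1.0)
        assert tr.intensity.iloc[0] == pytest.approx(0.91 + 0.09, rel=1e-9)

    def test_cryo_temperature_closed_form_value(self):
        spec = DecayTraceSpec(A1=0.37, tau1_s=0.87, A2=0.33, tau2_s=8.32, dt_s=0.01)
        tr = simulate_decay(spec, 2.0)
        expected = 0.37 / np.e + 0.33 * np.exp(-0.87 / 8.32)
        at = tr.intensity[np.isclose(tr.t_s, 0.87)].iloc[0]
        assert at == pytest.approx(expected, rel=1e-9)

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            DecayTraceSpec(A1=np.nan, tau1_s=1.0)

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError):
            DecayTraceSpec(A1=1.0, tau1_s=5.0, A2=0.5, tau2_s=1.0)

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_decay(DecayTraceSpec(A1=1.0, tau1_s=1.0), -1.0)

    def test_switching_trace_recovers_after_pulses(self):
        tr = simulate_switching_trace([5.0, 10.0], 15.0, tau_off_s=0.5)
        y = tr.intensity.to_numpy()
        t = tr.t_s.to_numpy()
        pre = y[np.argmin(np.abs(t - 4.9))]
        post = y[np.argmin(np.abs(t - 5.05))]
        assert post > 5 * max(pre, 1e-9)


def test_drift_models_have_zero_reference_frame(rng):
    for kind, kw in [("linear", {"rate_nm_per_frame": (0.5, 0, 0)}),
                     ("sinusoid", {"amplitude_nm": (30, 30, 0)}),
                     ("random_walk", {"step_nm": 1.0})]:
        trace = DriftModel(kind=kind, **kw).trace(100, rng)
        assert np.allclose(trace[0], 0.0)
        assert trace.shape == (100, 3)
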