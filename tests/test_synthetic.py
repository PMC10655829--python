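"""Synthetic-trial generator: analytic truth, rendering, traces, angles."""

import numpy as np
import pytest
from scipy.integrate import quad

from striderforce import (
    ConfigError,
    SceneParams,
    StrokeModel,
    detect_marker,
    render_frames,
    simulate_angle_series,
    simulate_direct_trace,
    simulate_propulsion,
)
from striderforce.kinematics import angular_velocity


class TestSimulatePropulsion:
    def test_half_sine_peak_speed_matches_quadrature(self, noiseless_scene):
        # closed form 2AT/pi against numerical quadrature of the thrust pulse
        model = StrokeModel(thrust_peak_ms2=40.3, thrust_duration_ms=34.0,
                            drag_coeff_uNs_per_mm=0.0)
        _, truth = simulate_propulsion(model, noiseless_scene, 80.0)
        A_mm = 40.3e3
        T = 0.034
        v_quad, _ = quad(lambda t: A_mm * np.sin(np.pi * t / T), 0.0, T)
        assert truth.v_max_mm_s == pytest.approx(2 * 40.3e3 * 0.034 / np.pi, rel=1e-12)
        assert truth.v_max_mm_s == pytest.approx(v_quad, rel=1e-9)
        assert truth.v_max_mm_s == pytest.approx(872.3, abs=0.1)

    def test_peak_acceleration_is_thrust_amplitude_at_midpoint(self, noiseless_scene):
        model = StrokeModel(thrust_peak_ms2=40.3, thrust_duration_ms=34.0,
                            start_ms=20.0)
        _, truth = simulate_propulsion(model, noiseless_scene, 80.0)
        assert truth.a_max_ms2 == 40.3
        assert truth.t_amax_ms == 20.0 + 17.0
        assert truth.accel_ms2.max() == pytest.approx(40.3, rel=1e-6)

    def test_zero_thrust_gives_constant_trajectory(self, noiseless_scene):
        model = StrokeModel(thrust_peak_ms2=0.0)
        trajectory, truth = simulate_propulsion(model, noiseless_scene, 80.0)
        assert np.ptp(trajectory.x_mm) == 0.0
        assert truth.v_max_mm_s == 0.0
        assert truth.a_max_ms2 == 0.0
        assert truth.f_prop_peak_uN == 0.0

    def test_sampled_series_agree_with_analytic_arrays(self, noiseless_scene):
        model = StrokeModel()
        trajectory, truth = simulate_propulsion(model, noiseless_scene, 80.0)
        # velocity by fine finite differences of the exact positions
        v_fd = np.gradient(trajectory.x_mm, trajectory.t_ms / 1000.0)
        interior = slice(2, -2)
        assert np.allclose(v_fd[interior], truth.velocity_mm_s[interior],
                           rtol=0.02, atol=5.0)

    def test_duration_too_short_raises(self, noiseless_scene):
        model = StrokeModel(start_ms=20.0, thrust_duration_ms=34.0)
        with pytest.raises(ConfigError):
            simulate_propulsion(model, noiseless_scene, 40.0)

    def test_scale_realism_of_defaults(self, noiseless_scene):
        # defaults must sit inside the observed 1-SD kinematic envelope
        _, truth = simulate_propulsion(StrokeModel(), noiseless_scene, 80.0)
        assert 700.0 <= truth.v_max_mm_s <= 1050.0
        assert 35.0 <= truth.a_max_ms2 <= 46.0


class TestRenderFrames:
    def test_brightest_pixel_at_integer_center(self, noiseless_scene):
        from striderforce import Trajectory

        scale = noiseless_scene.mm_per_px
        traj = Trajectory(t_ms=[0.0, 1.0], x_mm=[40 * scale, 41 * scale],
                          y_mm=[30 * scale, 30 * scale],
                          calibration=noiseless_scene.calibration)
        frames = render_frames(traj, noiseless_scene, seed=0)
        r, c = np.unravel_index(np.argmax(frames[1]), frames[1].shape)
        assert (r, c) == (30, 41)

    def test_deterministic_given_seed(self, default_config):
        traj, _ = simulate_propulsion(default_config.stroke,
                                      default_config.scene, 80.0)
        a = render_frames(traj, default_config.scene, seed=42)
        b = render_frames(traj, default_config.scene, seed=42)
        assert a.dtype == np.uint8
        assert np.array_equal(a, b)
        c = render_frames(traj, default_config.scene, seed=43)
        assert not np.array_equal(a, c)

    def test_zero_amplitude_blob_is_lost_everywhere(self):
        scene = SceneParams(blob_amplitude=0.0, noise_sigma=1.0)
        traj, _ = simulate_propulsion(StrokeModel(), scene, 80.0)
        frames = render_frames(traj, scene, seed=0)
        assert all(detect_marker(f) is None for f in frames[1:])

    def test_marker_out_of_view_raises(self):
        scene = SceneParams(frame_shape=(64, 64), mm_per_px=0.05)
        traj, _ = simulate_propulsion(StrokeModel(), scene, 80.0)
        with pytest.raises(ConfigError, match="field of view"):
            render_frames(traj, scene, seed=0)

    def test_calibration_square_only_in_first_frame(self, noiseless_scene):
        traj, _ = simulate_propulsion(StrokeModel(), noiseless_scene, 80.0)
        frames = render_frames(traj, noiseless_scene, seed=0)
        corner0 = frames[0][10:20, 10:20].astype(float)
        corner1 = frames[1][10:20, 10:20].astype(float)
        assert corner0.mean() > corner1.mean() + 10


class TestSimulateDirectTrace:
    def test_noiseless_peak_location_and_value(self):
        trace = simulate_direct_trace(f_peak_uN=2172.0, onset_ms=50.0,
                                      rise_ms=160.0, noise_uN=0.0)
        i = int(np.argmax(trace.force_uN))
        assert trace.force_uN[i] == pytest.approx(2172.0, rel=1e-12)
        assert trace.t_ms[i] == pytest.approx(210.0)
        assert np.all(trace.force_uN[trace.t_ms < 50.0] == 0.0)

    def test_zero_peak_gives_flat_baseline(self):
        trace = simulate_direct_trace(f_peak_uN=0.0, noise_uN=0.0)
        assert np.all(trace.force_uN == 0.0)

    def test_two_seeds_differ_only_in_noise(self):
        a = simulate_direct_trace(noise_uN=5.0, seed=1)
        b = simulate_direct_trace(noise_uN=5.0, seed=2)
        c = simulate_direct_trace(noise_uN=5.0, seed=1)
        assert np.array_equal(a.force_uN, c.force_uN)
        assert not np.array_equal(a.force_uN, b.force_uN)
        clean = simulate_direct_trace(noise_uN=0.0)
        assert np.abs(a.force_uN - clean.force_uN).max() < 5.0 * 6

    def test_invalid_sampling_rate_raises(self):
        with pytest.raises(ConfigError):
            simulate_direct_trace(fs_hz=0.0)


class TestSimulateAngleSeries:
    @pytest.mark.parametrize("theta0, omega", [(48.0, 1.95), (30.0, 1.0),
                                               (48.0, 0.73)])
    def test_angular_velocity_recovered_exactly(self, theta0, omega):
        angles = simulate_angle_series(theta0_deg=theta0,
                                       omega_deg_per_ms=omega,
                                       duration_ms=150.0)
        assert angular_velocity(angles) == pytest.approx(omega, abs=0.01)

    def test_long_tail_profile_plateaus(self):
        angles = simulate_angle_series(profile="long_tail", duration_ms=150.0)
        assert angles.theta_deg[-1] == angles.theta_deg.max()

    def test_symmetric_profile_descends_after_peak(self):
        angles = simulate_angle_series(profile="symmetric", duration_ms=150.0)
        assert angles.theta_deg[-1] < angles.theta_deg.max()

    def test_angles_stay_within_convention_bounds(self):
        angles = simulate_angle_series(duration_ms=300.0)
        assert angles.theta_deg.min() >= 0.0
        assert angles.theta_deg.max() <= 180.0

    def test_invalid_parameters_raise(self):
        with pytest.raises(ConfigError):
            simulate_angle_series(theta0_deg=95.0)
        with pytest.raises(ConfigError):
            simulate_angle_series(omega_deg_per_ms=0.0)
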