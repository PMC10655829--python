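"""Differentiation, stroke events and angular velocity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striderforce import (
    AngleSeries,
    Calibration,
    ConfigError,
    CrossingError,
    OnsetError,
    Trajectory,
    angular_velocity,
    arrival_time,
    detect_onset,
    differentiate,
    max_acceleration,
    max_speed,
)
from striderforce.synthetic import simulate_angle_series

CAL = Calibration(mm_per_px=0.1, source="test")


def make_trajectory(t_ms, x_mm, y_mm=None):
    y = np.zeros_like(np.asarray(x_mm)) if y_mm is None else y_mm
    return Trajectory(t_ms=t_ms, x_mm=x_mm, y_mm=y, calibration=CAL)


class TestDifferentiate:
    def test_pure_quadratic_recovered_exactly(self):
        # x = 1/2 a t^2 with a = 40.3 m/s^2: exact at every point
        t_ms = np.arange(100.0)
        a_mm_ms2 = 40.3e-3  # 40.3 m/s^2 in mm/ms^2
        x = 0.5 * a_mm_ms2 * t_ms**2
        series = differentiate(make_trajectory(t_ms, x), window_pts=7)
        assert series.accel_ms2 == pytest.approx(np.full(100, 40.3), abs=1e-6)
        assert series.speed_mm_s == pytest.approx(a_mm_ms2 * t_ms * 1e3, abs=1e-6)

    @given(
        c0=st.floats(-10, 10), c1=st.floats(-5, 5), c2=st.floats(-1, 1),
        window=st.sampled_from([3, 5, 7, 9, 11]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_polynomials_up_to_degree_two_exact_for_any_window(self, c0, c1, c2, window):
        t_ms = np.arange(40.0)
        x = c0 + c1 * t_ms + c2 * t_ms**2
        series = differentiate(make_trajectory(t_ms, x), window_pts=window)
        sign = 1.0 if x[-1] >= x[0] else -1.0  # projection flips with net motion
        assert series.speed_mm_s == pytest.approx(
            sign * (c1 + 2 * c2 * t_ms) * 1e3, abs=2e-5 * max(1, abs(c2) * 1e3))
        assert series.accel_ms2 == pytest.approx(
            np.full(40, sign * 2 * c2 * 1e3), abs=1e-5 * max(1, abs(c2) * 1e3))

    def test_constant_position_yields_zero_kinematics(self):
        t_ms = np.arange(30.0)
        series = differentiate(make_trajectory(t_ms, np.full(30, 3.3)))
        assert np.all(series.speed_mm_s == 0.0)
        assert np.all(series.accel_ms2 == 0.0)

    def test_scaling_positions_by_power_of_two_scales_derivatives_exactly(self):
        t_ms = np.arange(50.0)
        x = np.sin(t_ms / 7.0) + 0.02 * t_ms
        base = differentiate(make_trajectory(t_ms, x))
        scaled = differentiate(make_trajectory(t_ms, 4.0 * x))
        assert np.array_equal(scaled.speed_mm_s, 4.0 * base.speed_mm_s)
        assert np.array_equal(scaled.accel_ms2, 4.0 * base.accel_ms2)

    def test_half_sine_peak_acceleration_within_one_percent(self, noiseless_trial):
        _, trajectory, truth, _ = noiseless_trial
        series = differentiate(trajectory, window_pts=7)
        a_max, t_peak = max_acceleration(series)
        assert a_max == pytest.approx(truth.a_max_ms2, rel=0.01)
        assert t_peak == pytest.approx(truth.t_amax_ms, abs=2.0)

    def test_too_few_points_raises(self):
        t_ms = np.arange(5.0)
        with pytest.raises(ConfigError):
            differentiate(make_trajectory(t_ms, t_ms**2), window_pts=7)

    def test_even_window_rejected(self):
        t_ms = np.arange(20.0)
        with pytest.raises(ConfigError):
            differentiate(make_trajectory(t_ms, t_ms), window_pts=6)

    def test_propulsion_axis_is_net_displacement_direction(self):
        t_ms = np.arange(20.0)
        traj = make_trajectory(t_ms, 3.0 * t_ms, 4.0 * t_ms)
        series = differentiate(traj)
        assert series.axis == pytest.approx([0.6, 0.8])


class TestSeriesExtrema:
    def test_monotone_ramp_peaks_at_end(self):
        t_ms = np.arange(30.0)
        series = differentiate(make_trajectory(t_ms, 0.01 * t_ms**2))
        v, tv = max_speed(series)
        assert tv == t_ms[-1]

    def test_all_zero_series_returns_first_timestamp(self):
        t_ms = np.arange(30.0)
        series = differentiate(make_trajectory(t_ms, np.zeros(30)))
        assert max_speed(series) == (0.0, 0.0)
        assert max_acceleration(series) == (0.0, 0.0)


class TestDetectOnset:
    def test_step_after_flat_baseline(self):
        t = np.arange(50.0)
        v = np.where(t >= 30.0, 5.0, 0.0)
        assert detect_onset(t, v, baseline_ms=20.0) == 30.0

    def test_noiseless_half_sine_onset_near_thrust_start(self, noiseless_trial):
        _, trajectory, truth, _ = noiseless_trial
        series = differentiate(trajectory)
        onset = detect_onset(series.t_ms, series.accel_ms2, baseline_ms=15.0)
        assert onset == pytest.approx(20.0, abs=2.0)

    def test_flat_series_raises(self):
        t = np.arange(50.0)
        with pytest.raises(OnsetError):
            detect_onset(t, np.zeros(50), baseline_ms=20.0)

    def test_short_baseline_raises(self):
        t = np.arange(50.0)
        with pytest.raises(ConfigError):
            detect_onset(t, t, baseline_ms=3.0)


class TestArrivalTime:
    def test_half_sine_arrival_is_half_thrust_duration(self, noiseless_trial):
        _, trajectory, truth, _ = noiseless_trial
        series = differentiate(trajectory)
        onset = detect_onset(series.t_ms, series.accel_ms2, baseline_ms=15.0)
        events = arrival_time(series.t_ms, series.accel_ms2, onset)
        assert events.arrival_ms == pytest.approx(34.0 / 2, abs=2.0)

    def test_peak_at_onset_gives_zero_arrival(self):
        t = np.arange(20.0)
        v = np.concatenate([[9.0], np.zeros(19)])
        events = arrival_time(t, v, onset_ms=0.0)
        assert events.arrival_ms == 0.0

    def test_peak_before_onset_raises(self):
        t = np.arange(20.0)
        v = np.concatenate([[9.0], np.zeros(19)])
        with pytest.raises(ConfigError):
            arrival_time(t, v, onset_ms=5.0)


class TestAngularVelocity:
    def test_linear_crossing(self):
        # 30 deg start, 90 deg reached at 60 ms -> 1.0 deg/ms
        t = np.arange(0.0, 100.0, 1.0)
        theta = np.minimum(30.0 + 1.0 * t, 140.0)
        assert angular_velocity(AngleSeries(t, theta)) == pytest.approx(1.0)

    def test_crossing_between_samples_interpolated(self):
        t = np.array([0.0, 10.0, 20.0])
        theta = np.array([40.0, 80.0, 120.0])  # crosses 90 at 12.5 ms
        omega = angular_velocity(AngleSeries(t, theta))
        assert omega == pytest.approx(50.0 / 12.5)

    def test_steep_start_near_ninety_is_finite(self):
        t = np.array([0.0, 1.0, 2.0])
        theta = np.array([89.9, 95.0, 100.0])
        omega = angular_velocity(AngleSeries(t, theta))
        assert np.isfinite(omega) and omega > 0

    def test_capped_series_never_crossing_raises(self):
        angles = simulate_angle_series(theta0_deg=40.0, theta_peak_deg=85.0,
                                       profile="long_tail")
        with pytest.raises(CrossingError):
            angular_velocity(angles)

    def test_initial_angle_at_or_above_ninety_raises(self):
        t = np.arange(10.0)
        with pytest.raises(ConfigError):
            angular_velocity(AngleSeries(t, np.full(10, 92.0)))
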