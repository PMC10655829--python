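"""Trajectory differentiation, stroke-event timing and leg angular velocity.

The indirect force estimate rests on the body's peak acceleration during one
rowing stroke.  Raw finite differences of a 0.1 mm-resolution track sampled at
1,000 fps are useless at the second derivative, so velocity and acceleration
come from a local least-squares quadratic (Savitzky-Golay-type) fit over a
sliding window.  Stroke onset is a sustained threshold crossing above the
pre-stroke baseline; the maximum-force arrival time is the lag from onset to
the series maximum.  Leg angular velocity follows the convention
``omega = (90 deg - theta(0)) / dt`` where ``dt`` is the time the middle-leg
angle takes to first reach 90 deg from the body axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, CrossingError, OnsetError
from .tracking import Trajectory

__all__ = [
    "KinematicSeries",
    "StrokeEvents",
    "AngleSeries",
    "differentiate",
    "max_speed",
    "max_acceleration",
    "detect_onset",
    "arrival_time",
    "angular_velocity",
]


@dataclass
class KinematicSeries:
    """Signed speed and acceleration projected onto the propulsion axis."""

    t_ms: np.ndarray
    speed_mm_s: np.ndarray
    accel_ms2: np.ndarray
    window_pts: int
    axis: np.ndarray  # unit vector of net displacement (x, y)

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass(frozen=True)
class StrokeEvents:
    """Timing of one rowing stroke: onset, peak, and the arrival lag."""

    onset_ms: float
    t_peak_ms: float
    arrival_ms: float
    peak_value: float

    def __post_init__(self) -> None:
        if self.arrival_ms < 0:
            raise ConfigError("arrival_ms must be nonnegative")


@dataclass
class AngleSeries:
    """Middle-leg angle theta_ML(t) in degrees (0 = folded along the body)."""

    t_ms: np.ndarray
    theta_deg: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        if len(self.t_ms) != len(self.theta_deg):
            raise ConfigError("t_ms and theta_deg must have equal length")
        if len(self.theta_deg) and (
            self.theta_deg.min() < 0 or self.theta_deg.max() > 180
        ):
            raise ConfigError("theta must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return len(self.t_ms)


def differentiate(trajectory: Trajectory, window_pts: int = 7) -> KinematicSeries:
    """Differentiate a trajectory along its propulsion axis.

    The propulsion axis is the unit vector of the net displacement (last minus
    first position); the study analyses straight forward propulsion, so this
    is well defined.  Positions are projected onto the axis and a centred
    least-squares quadratic over ``window_pts`` samples provides the first and
    second derivative at each interior point; near the ends the window shrinks
    to a one-sided window of at least 3 points.  Derivatives of polynomials of
    degree <= 2 are therefore exact for any window.

    Returns speed in mm/s and acceleration in m/s^2 (the units in which the
    published peak values are quoted).
    """
    if window_pts < 3 or window_pts % 2 == 0:
        raise ConfigError(f"window_pts must be odd and >= 3, got {window_pts}")
    n = len(trajectory)
    if n < window_pts:
        raise ConfigError(f"trajectory has {n} points, need >= {window_pts}")

    pos = trajectory.positions_mm
    disp = pos[-1] - pos[0]
    norm = float(np.hypot(*disp))
    if norm == 0.0:
        # direction of travel undefined; fall back to +x so that a perfectly
        # stationary marker yields identically zero speed and acceleration
        if not np.allclose(pos, pos[0]):
            raise ConfigError("zero net displacement: propulsion axis undefined")
        axis = np.array([1.0, 0.0])
    else:
        axis = disp / norm
    s = pos @ axis  # mm along the axis
    t = trajectory.t_ms

    half = window_pts // 2
    vel = np.empty(n)
    acc = np.empty(n)
    # cache the pseudo-inverse per window shape: all interior windows share one
    solvers: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        while hi - lo < 3:  # a quadratic needs at least 3 samples
            if hi < n:
                hi += 1
            else:
                lo -= 1
        key = (i - lo, hi - i)
        pinv = solvers.get(key)
        if pinv is None:
            tau = t[lo:hi] - t[i]
            design = np.column_stack([tau**2, tau, np.ones_like(tau)])
            pinv = np.linalg.pinv(design)
            solvers[key] = pinv
        # fit relative to s[i]: constants differentiate to exactly zero
        c2, c1, _ = pinv @ (s[lo:hi] - s[i])
        vel[i] = c1  # mm/ms == m/s
        acc[i] = 2.0 * c2  # mm/ms^2 == 1000 m/s^2

    return KinematicSeries(
        t_ms=t.copy(),
        speed_mm_s=vel * 1000.0,
        accel_ms2=acc * 1000.0,
        window_pts=window_pts,
        axis=axis,
    )


def _series_max(t_ms: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        raise ConfigError("empty series")
    i = int(np.argmax(values))  # ties resolve to the earliest sample
    return float(values[i]), float(t_ms[i])


def max_speed(series: KinematicSeries) -> tuple[float, float]:
    """Maximum signed projected speed (mm/s) and its timestamp (ms)."""
    return _series_max(series.t_ms, series.speed_mm_s)


def max_acceleration(series: KinematicSeries) -> tuple[float, float]:
    """Maximum signed projected acceleration (m/s^2) and its timestamp (ms)."""
    return _series_max(series.t_ms, series.accel_ms2)


def detect_onset(t_ms: np.ndarray, values: np.ndarray, baseline_ms: float,
                 k_sigma: float = 3.0, sustain_pts: int = 3) -> float:
    """Locate stroke onset as a sustained excursion above the baseline.

    The baseline window ``t < baseline_ms`` must precede any motion and
    contain at least 5 samples.  Onset is the first sample of the first run of
    ``sustain_pts`` consecutive samples exceeding
    ``baseline_mean + k_sigma * baseline_SD``.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    values = np.asarray(values, dtype=float)
    base = values[t_ms < baseline_ms]
    if len(base) < 5:
        raise ConfigError(
            f"baseline window ({baseline_ms} ms) holds {len(base)} samples, need >= 5"
        )
    threshold = float(base.mean()) + k_sigma * float(base.std(ddof=1))
    above = values > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= sustain_pts:
            return float(t_ms[i - sustain_pts + 1])
    raise OnsetError(
        f"no {sustain_pts}-sample excursion above {threshold:.6g} found"
    )


def arrival_time(t_ms: np.ndarray, values: np.ndarray, onset_ms: float) -> StrokeEvents:
    """Maximum-force arrival: lag from stroke onset to the series maximum."""
    t_ms = np.asarray(t_ms, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (t_ms[0] <= onset_ms <= t_ms[-1]):
        raise ConfigError(f"onset {onset_ms} ms outside series span")
    peak_value, t_peak = _series_max(t_ms, values)
    after = t_ms >= onset_ms
    peak_after, t_peak_after = _series_max(t_ms[after], values[after])
    if peak_after < peak_value:
        raise ConfigError(
            f"series maximum at {t_peak} ms precedes onset at {onset_ms} ms"
        )
    return StrokeEvents(
        onset_ms=float(onset_ms),
        t_peak_ms=t_peak_after,
        arrival_ms=t_peak_after - float(onset_ms),
        peak_value=peak_after,
    )


def angular_velocity(angles: AngleSeries) -> float:
    """Leg rowing angular velocity in deg/ms.

    ``omega = (90 - theta(0)) / dt`` with ``dt`` the first crossing of 90 deg,
    located by linear interpolation between the bracketing samples so the
    estimate carries no frame-rate-dependent bias.
    """
    theta = angles.theta_deg
    t = angles.t_ms
    if len(theta) < 2:
        raise ConfigError("angle series needs >= 2 samples")
    theta0 = float(theta[0])
    if theta0 >= 90.0:
        raise ConfigError(f"initial angle {theta0} deg must be below 90 deg")
    above = np.nonzero(theta >= 90.0)[0]
    if len(above) == 0:
        raise CrossingError("leg angle never reaches 90 deg")
    i = int(above[0])
    if theta[i] == 90.0:
        t_cross = float(t[i])
    else:
        frac = (90.0 - theta[i - 1]) / (theta[i] - theta[i - 1])
        t_cross = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    dt = t_cross - float(t[0])
    return (90.0 - theta0) / dt
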