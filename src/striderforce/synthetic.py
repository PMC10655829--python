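"""Ground-truthed synthetic inputs: frame stacks, force traces, angle series.

No footage or transducer recordings from the original experiments are
deposited anywhere, so every downstream stage is exercised on synthetic
trials whose generative parameters sit at the published scale: a ~36 mg
insect, a single 20-40 ms middle-leg thrust reaching ~40 m/s^2 peak
acceleration and ~860 mm/s peak speed, filmed at 1,000 fps with a 10 mm
calibration square in view.

The thrust is a half-sine acceleration pulse ``a(t) = A sin(pi (t-t0)/T)``
on ``t0 <= t <= t0+T`` — the simplest two-parameter shape consistent with
the published peak-acceleration / peak-speed / arrival-time relations —
followed by exponential linear-drag coasting.  Velocity and position are
exact piecewise integrals, so the ground-truth extrema are analytic:
``v_max = 2 A T / pi`` at the end of the thrust and ``a_max = A`` at its
midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .forces import ForceTrace
from .kinematics import AngleSeries
from .tracking import Calibration, Trajectory

__all__ = [
    "StrokeModel",
    "SceneParams",
    "GroundTruth",
    "simulate_propulsion",
    "render_frames",
    "simulate_direct_trace",
    "simulate_angle_series",
]


@dataclass(frozen=True)
class StrokeModel:
    """Generative model of one rowing stroke.

    Defaults reproduce the published kinematic scale: 35.9 mg body mass,
    40.3 m/s^2 peak thrust acceleration, 34 ms thrust duration (giving
    ``v_max = 2AT/pi = 872 mm/s``), and a mild linear drag that decelerates
    the body after the stroke.
    """

    mass_mg: float = 35.9
    thrust_peak_ms2: float = 40.3
    thrust_duration_ms: float = 34.0
    drag_coeff_uNs_per_mm: float = 0.2
    start_ms: float = 20.0
    rest_ms: float = 20.0

    def __post_init__(self) -> None:
        if not self.mass_mg > 0:
            raise ConfigError(f"mass must be positive, got {self.mass_mg} mg")
        if self.thrust_peak_ms2 < 0:
            raise ConfigError("thrust peak must be nonnegative")
        if not self.thrust_duration_ms > 0:
            raise ConfigError("thrust duration must be positive")
        if self.drag_coeff_uNs_per_mm < 0:
            raise ConfigError("drag coefficient must be nonnegative")
        if self.start_ms < 0:
            raise ConfigError("start_ms must be nonnegative")
        if self.rest_ms > self.start_ms:
            raise ConfigError("rest_ms cannot exceed start_ms")


@dataclass(frozen=True)
class SceneParams:
    """Imaging-scene parameters for rendering synthetic footage.

    The defaults put a sigma = 2 px Gaussian marker of peak 180 DN on a
    20 DN background in a 256 x 256 frame at 0.2 mm/px, and draw the 10 mm
    calibration square as a 50 px filled square.  The square is rendered
    dimmer than the marker (``square_amplitude``) so that it sits below the
    marker-detection threshold while remaining easy to segment for scale
    calibration.
    """

    fps: float = 1000.0
    frame_shape: tuple[int, int] = (256, 256)  # rows, cols
    mm_per_px: float = 0.2
    blob_sigma_px: float = 2.0
    blob_amplitude: float = 180.0
    background: float = 20.0
    noise_sigma: float = 2.0
    square_side_px: int = 50
    square_amplitude: float = 60.0

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        if not 0 < self.blob_amplitude + self.background <= 255:
            raise ConfigError("blob peak must land in (0, 255] DN")
        if self.noise_sigma < 0:
            raise ConfigError("noise sigma must be nonnegative")
        if not self.mm_per_px > 0:
            raise ConfigError("mm_per_px must be positive")
        if not self.blob_sigma_px > 0:
            raise ConfigError("blob sigma must be positive")

    @property
    def calibration(self) -> Calibration:
        return Calibration(mm_per_px=self.mm_per_px, source="synthetic scene")


@dataclass
class GroundTruth:
    """Analytic truth record for one synthetic trial."""

    t_ms: np.ndarray
    positions_mm: np.ndarray  # (n, 2)
    velocity_mm_s: np.ndarray
    accel_ms2: np.ndarray
    v_max_mm_s: float
    a_max_ms2: float
    t_amax_ms: float
    f_prop_peak_uN: float

    def as_dict(self) -> dict:
        return {
            "v_max_mm_s": self.v_max_mm_s,
            "a_max_ms2": self.a_max_ms2,
            "t_amax_ms": self.t_amax_ms,
            "f_prop_peak_uN": self.f_prop_peak_uN,
        }


def simulate_propulsion(model: StrokeModel, scene: SceneParams,
                        duration_ms: float = 80.0,
                        seed: int | None = None) -> tuple[Trajectory, GroundTruth]:
    """Integrate one rowing stroke exactly and sample it at the frame rate.

    Motion is 1-D along +x.  Acceleration is the half-sine thrust during the
    stroke window, zero before it, and linear-drag deceleration
    ``a = -(c/m) v`` afterwards.  Position and velocity are exact piecewise
    integrals evaluated at ``t_i = i / fps``; the ground-truth extrema are
    analytic, not read off the sampled arrays.  ``seed`` is accepted for
    interface symmetry but unused: the kinematics are deterministic (all
    randomness lives in :func:`render_frames` and the trace generators).
    """
    del seed
    if duration_ms < model.start_ms + model.thrust_duration_ms:
        raise ConfigError(
            f"duration {duration_ms} ms shorter than stroke end "
            f"{model.start_ms + model.thrust_duration_ms} ms"
        )
    fps = scene.fps
    n = int(round(duration_ms * fps / 1000.0)) + 1
    t_ms = np.arange(n) * 1000.0 / fps

    rows, cols = scene.frame_shape
    x0 = 0.1 * cols * scene.mm_per_px
    y0 = 0.5 * (rows - 1) * scene.mm_per_px

    A = model.thrust_peak_ms2 * 1000.0  # mm/s^2
    T = model.thrust_duration_ms / 1000.0  # s
    t0 = model.start_ms / 1000.0
    ts = t_ms / 1000.0
    omega = math.pi / T
    # drag rate: c [μN s/mm] * v [mm/s] = force in μN; μN/mg = m/s^2
    k = 1000.0 * model.drag_coeff_uNs_per_mm / model.mass_mg  # 1/s

    v1 = 2.0 * A * T / math.pi  # speed at thrust end, mm/s
    x1 = x0 + A * T**2 / math.pi  # position at thrust end, mm

    x = np.full(n, x0)
    v = np.zeros(n)
    a = np.zeros(n)

    thrust = (ts >= t0) & (ts <= t0 + T)
    tau = ts[thrust] - t0
    a[thrust] = A * np.sin(omega * tau)
    v[thrust] = (A / omega) * (1.0 - np.cos(omega * tau))
    x[thrust] = x0 + (A / omega) * (tau - np.sin(omega * tau) / omega)

    coast = ts > t0 + T
    tau2 = ts[coast] - (t0 + T)
    if k > 0:
        v[coast] = v1 * np.exp(-k * tau2)
        x[coast] = x1 + (v1 / k) * (1.0 - np.exp(-k * tau2))
        a[coast] = -k * v[coast]
    else:
        v[coast] = v1
        x[coast] = x1 + v1 * tau2

    trajectory = Trajectory(
        t_ms=t_ms, x_mm=x, y_mm=np.full(n, y0), calibration=scene.calibration
    )
    truth = GroundTruth(
        t_ms=t_ms,
        positions_mm=np.column_stack([x, np.full(n, y0)]),
        velocity_mm_s=v,
        accel_ms2=a / 1000.0,
        v_max_mm_s=v1 if model.thrust_peak_ms2 > 0 else 0.0,
        a_max_ms2=model.thrust_peak_ms2,
        t_amax_ms=model.start_ms + model.thrust_duration_ms / 2.0,
        f_prop_peak_uN=model.mass_mg * model.thrust_peak_ms2,
    )
    return trajectory, truth


def render_frames(trajectory: Trajectory, scene: SceneParams,
                  seed: int | None = None) -> np.ndarray:
    """Render a trajectory into an 8-bit grayscale frame stack.

    Each frame is ``background + Gaussian blob + i.i.d. Gaussian noise``,
    clipped and quantised to [0, 255].  The blob is centred at the mm
    position converted to px (x = column, y = row, top-left origin).  A
    filled calibration square of side ``square_side_px`` is drawn near the
    top-left corner of frame 0 only.  Deterministic for a given seed.
    """
    rows, cols = scene.frame_shape
    cx = trajectory.x_mm / scene.mm_per_px
    cy = trajectory.y_mm / scene.mm_per_px
    if (cx.min() < 0 or cx.max() > cols - 1 or cy.min() < 0 or cy.max() > rows - 1):
        raise ConfigError("marker leaves the field of view")

    rng = np.random.default_rng(seed)
    rr = np.arange(rows)
    cc = np.arange(cols)
    n = len(trajectory)
    stack = np.empty((n, rows, cols), dtype=np.uint8)
    inv2s2 = 1.0 / (2.0 * scene.blob_sigma_px**2)
    for i in range(n):
        gy = np.exp(-((rr - cy[i]) ** 2) * inv2s2)
        gx = np.exp(-((cc - cx[i]) ** 2) * inv2s2)
        img = scene.background + scene.blob_amplitude * np.outer(gy, gx)
        if i == 0 and scene.square_side_px > 0:
            margin = 4
            side = scene.square_side_px
            img[margin:margin + side, margin:margin + side] = (
                scene.background + scene.square_amplitude
            )
        if scene.noise_sigma > 0:
            img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)
        stack[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return stack


def simulate_direct_trace(f_peak_uN: float = 2172.0, onset_ms: float = 50.0,
                          rise_ms: float = 160.0, decay_ms: float = 150.0,
                          fs_hz: float = 1000.0, noise_uN: float = 0.0,
                          duration_ms: float = 600.0,
                          seed: int | None = None) -> ForceTrace:
    """Synthesize a transducer trace with the published direct-trial shape.

    Zero baseline, raised-cosine rise to ``f_peak_uN`` over ``rise_ms``, then
    exponential decay (time constant ``decay_ms``) — the asymmetric
    long-tailed profile seen when the hooked leg keeps pushing the probe.
    The noiseless peak sits exactly at ``onset_ms + rise_ms``.
    """
    if not fs_hz > 0:
        raise ConfigError(f"fs_hz must be positive, got {fs_hz}")
    if not onset_ms + rise_ms < duration_ms:
        raise ConfigError("duration must cover onset + rise")
    if rise_ms <= 0 or decay_ms <= 0:
        raise ConfigError("rise and decay times must be positive")

    n = int(round(duration_ms * fs_hz / 1000.0)) + 1
    t_ms = np.arange(n) * 1000.0 / fs_hz
    f = np.zeros(n)
    t_peak = onset_ms + rise_ms
    rising = (t_ms >= onset_ms) & (t_ms <= t_peak)
    f[rising] = 0.5 * f_peak_uN * (1.0 - np.cos(np.pi * (t_ms[rising] - onset_ms) / rise_ms))
    tail = t_ms > t_peak
    f[tail] = f_peak_uN * np.exp(-(t_ms[tail] - t_peak) / decay_ms)
    if noise_uN > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_uN, size=n)
    return ForceTrace(t_ms=t_ms, force_uN=f, fs_hz=fs_hz)


def simulate_angle_series(theta0_deg: float = 48.0, profile: str = "symmetric",
                          omega_deg_per_ms: float = 1.95, fps: float = 1000.0,
                          duration_ms: float = 120.0,
                          theta_peak_deg: float = 135.0) -> AngleSeries:
    """Synthesize a middle-leg angle series crossing 90 deg at a known rate.

    The angle rises linearly from ``theta0_deg`` at ``omega_deg_per_ms`` so
    the 90 deg crossing falls at exactly ``(90 - theta0) / omega`` and the
    angular-velocity estimator recovers omega exactly.  After the peak angle
    the ``symmetric`` profile descends at the same rate (the free-rowing
    half-sine-like sweep) while ``long_tail`` holds a plateau (the hooked leg
    pressed against the probe).
    """
    if not 0 < theta0_deg < 90:
        raise ConfigError(f"theta0 must lie in (0, 90) deg, got {theta0_deg}")
    if omega_deg_per_ms <= 0:
        raise ConfigError(f"omega must be positive, got {omega_deg_per_ms}")
    if not theta0_deg < theta_peak_deg <= 180:
        raise ConfigError("theta_peak must lie in (theta0, 180] deg")
    if profile not in ("symmetric", "long_tail"):
        raise ConfigError(f"unknown profile {profile!r}")

    n = int(round(duration_ms * fps / 1000.0)) + 1
    t_ms = np.arange(n) * 1000.0 / fps
    t_top = (theta_peak_deg - theta0_deg) / omega_deg_per_ms
    theta = theta0_deg + omega_deg_per_ms * t_ms
    if profile == "symmetric":
        down = theta_peak_deg - omega_deg_per_ms * (t_ms - t_top)
        theta = np.where(t_ms > t_top, np.maximum(down, theta0_deg), theta)
    else:
        theta = np.minimum(theta, theta_peak_deg)
    return AngleSeries(t_ms=t_ms, theta_deg=theta)
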