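"""End-to-end workflows: simulate, indirect (video) route, direct (probe) route.

The indirect route mirrors the free-locomotion experiment: track the pronotum
marker, differentiate, take the peak acceleration, and apportion ``m a``
between the two middle legs.  The direct route mirrors the hooked-leg
experiment: find the transducer peak, scale it to the leg tip by the
moment-arm ratio, and attach per-length and resultant values.  ``demo_checks``
re-derives every published worked-example number from constants and seeded
synthetic runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import reference as ref
from .energy_stats import loss_fraction, summarize
from .errors import StriderforceError
from .forces import (
    ForceResult,
    ForceTrace,
    middle_leg_from_propellant,
    peak_force,
    per_unit_length,
    propellant_force,
    resultant_force,
    tip_force_from_hook,
)
from .io import RunConfig
from .kinematics import (
    StrokeEvents,
    angular_velocity,
    arrival_time,
    detect_onset,
    differentiate,
    max_acceleration,
    max_speed,
)
from .synthetic import (
    render_frames,
    simulate_angle_series,
    simulate_direct_trace,
    simulate_propulsion,
)
from .tracking import track_sequence
from .util import report_round

logger = logging.getLogger("striderforce")

__all__ = ["IndirectOutcome", "DirectOutcome", "run_indirect", "run_direct",
           "simulate_trial", "demo_checks"]


@dataclass
class IndirectOutcome:
    forces: ForceResult
    events: StrokeEvents
    a_max_ms2: float
    v_max_mm_s: float
    t_amax_ms: float


@dataclass
class DirectOutcome:
    forces: ForceResult
    events: StrokeEvents


def _stage(name: str):
    logger.info("stage: %s", name)


def simulate_trial(config: RunConfig):
    """Generate one synthetic trial: frames, ground truth, trace, angles."""
    _stage("simulate")
    trajectory, truth = simulate_propulsion(config.stroke, config.scene,
                                            duration_ms=config.duration_ms,
                                            seed=config.seed)
    frames = render_frames(trajectory, config.scene, seed=config.seed)
    trace = simulate_direct_trace(
        f_peak_uN=config.trace_peak_uN, onset_ms=config.trace_onset_ms,
        rise_ms=config.trace_rise_ms, decay_ms=config.trace_decay_ms,
        fs_hz=config.scene.fps, noise_uN=config.trace_noise_uN,
        duration_ms=config.trace_duration_ms, seed=config.seed,
    )
    angles = simulate_angle_series(fps=config.scene.fps,
                                   duration_ms=config.duration_ms)
    return frames, truth, trace, angles


def run_indirect(frames: np.ndarray, config: RunConfig) -> IndirectOutcome:
    """Video route: frames -> trajectory -> kinematics -> forces."""
    _stage("track")
    trajectory = track_sequence(frames, config.scene.calibration,
                                fps=config.scene.fps,
                                threshold_frac=config.threshold_frac,
                                min_area_px=config.min_area_px,
                                gap_limit=config.gap_limit)
    _stage("differentiate")
    series = differentiate(trajectory, window_pts=config.window_pts)
    a_max, t_amax = max_acceleration(series)
    v_max, _ = max_speed(series)
    _stage("events")
    onset = detect_onset(series.t_ms, series.accel_ms2, config.baseline_ms,
                         k_sigma=config.k_sigma, sustain_pts=config.sustain_pts)
    events = arrival_time(series.t_ms, series.accel_ms2, onset)
    _stage("forces")
    f_prop = propellant_force(config.geometry.mass_mg, a_max)
    f_mlindir = middle_leg_from_propellant(f_prop,
                                           apportionment=config.apportionment,
                                           n_legs=config.n_legs)
    forces = ForceResult(
        f_prop_uN=f_prop,
        f_mlindir_uN=f_mlindir,
        per_length_uN_mm=per_unit_length(f_mlindir,
                                         config.geometry.contact_length_mm),
    )
    return IndirectOutcome(forces=forces, events=events, a_max_ms2=a_max,
                           v_max_mm_s=v_max, t_amax_ms=t_amax)


def run_direct(trace: ForceTrace, config: RunConfig) -> DirectOutcome:
    """Probe route: trace -> peak -> tip force -> per-length and resultant."""
    _stage("peak_force")
    f_mlbap, events = peak_force(trace, config.trace_baseline_ms,
                                 k_sigma=config.k_sigma,
                                 sustain_pts=config.sustain_pts)
    _stage("forces")
    f_mldir = tip_force_from_hook(f_mlbap, config.geometry)
    forces = ForceResult(
        f_mlbap_uN=f_mlbap,
        f_mldir_uN=f_mldir,
        per_length_uN_mm=per_unit_length(f_mldir,
                                         config.geometry.contact_length_mm),
        resultant_uN=resultant_force(f_mldir, config.vertical_factor),
    )
    return DirectOutcome(forces=forces, events=events)


def demo_checks(seed: int = 0) -> list[dict]:
    """Recompute every published worked-example number; return check records.

    Each record holds the check name, the freshly computed value, the
    published value it must match, the comparison tolerance and a pass flag.
    The first block is pure constant arithmetic; the second is a seeded
    synthetic parameter-recovery run through the full pipeline.
    """
    checks: list[dict] = []

    def add(name, value, expected, tol):
        checks.append({
            "name": name, "value": value, "expected": expected, "tol": tol,
            "ok": abs(value - expected) <= tol,
        })

    # -- worked examples from published constants -------------------------
    f_mlindir = middle_leg_from_propellant(ref.F_PROP_IMG_UN,
                                           ref.APPORTIONMENT, ref.N_MIDDLE_LEGS)
    add("indirect middle-leg force (μN)", report_round(f_mlindir), 493, 0)
    add("direct force per unit length (μN/mm)",
        report_round(per_unit_length(ref.F_MLDIR_UN, ref.CONTACT_LENGTH_MM)),
        87, 0)
    add("indirect force per unit length (μN/mm)",
        report_round(per_unit_length(ref.F_MLINDIR_UN, ref.CONTACT_LENGTH_MM)),
        45, 0)
    res = resultant_force(ref.F_MLDIR_UN, ref.VERTICAL_FACTOR)
    add("resultant middle-leg force (μN)", report_round(res), 1146, 0)
    add("resultant per unit length (μN/mm)",
        report_round(per_unit_length(res, ref.CONTACT_LENGTH_MM)), 104, 0)
    add("arrival-time ratio direct/indirect",
        report_round(ref.T_MAXF_DIR_MS / ref.T_MAXF_INDIR_MS, 1), 7.6, 0)
    add("angular-velocity ratio indirect/direct",
        report_round(ref.OMEGA_ML_INDIR / ref.OMEGA_ML_DIR, 1), 2.7, 0)
    weights = summarize(ref.INSECT_WEIGHTS_MG)
    add("insect mass mean (mg)", report_round(weights.mean, 1), 35.9, 0)
    add("insect mass sample SD (mg)", report_round(weights.sd, 1), 3.5, 0)
    add("force loss fraction",
        loss_fraction(ref.F_MLDIR_UN, ref.F_MLINDIR_UN), 0.484, 0.001)

    # -- seeded synthetic recovery ----------------------------------------
    config = RunConfig(seed=seed)
    frames, truth, _, _ = simulate_trial(config)
    outcome = run_indirect(frames, config)
    add("recovered peak acceleration (m/s²), noisy render",
        outcome.a_max_ms2, truth.a_max_ms2, 0.05 * truth.a_max_ms2)
    add("recovered peak speed (mm/s), noisy render",
        outcome.v_max_mm_s, truth.v_max_mm_s, 0.05 * truth.v_max_mm_s)

    # noiseless, drag-free stroke: the closed form v_max = 2AT/pi is exact
    # truth here, so the pipeline must agree tightly with it
    base = config.to_dict()
    noiseless = RunConfig.from_dict({
        **base,
        "scene": {**base["scene"], "noise_sigma": 0.0},
        "stroke": {**base["stroke"], "drag_coeff_uNs_per_mm": 0.0},
    })
    frames0, truth0, _, _ = simulate_trial(noiseless)
    out0 = run_indirect(frames0, noiseless)
    add("recovered peak acceleration (m/s²), noiseless",
        out0.a_max_ms2, truth0.a_max_ms2, 0.01 * truth0.a_max_ms2)
    add("recovered peak speed (mm/s), noiseless closed form",
        out0.v_max_mm_s, truth0.v_max_mm_s, 0.005 * truth0.v_max_mm_s)

    trace = simulate_direct_trace(noise_uN=0.0, fs_hz=1000.0)
    direct = run_direct(trace, config)
    add("recovered transducer peak (μN), noiseless trace",
        direct.forces.f_mlbap_uN, 2172.0, 1e-9)
    add("recovered arrival time (ms), noiseless trace",
        direct.events.arrival_ms, 160.0, 2.0)

    for omega, label in ((ref.OMEGA_ML_INDIR, "indirect"),
                         (ref.OMEGA_ML_DIR, "direct")):
        profile = "symmetric" if label == "indirect" else "long_tail"
        angles = simulate_angle_series(omega_deg_per_ms=omega, profile=profile)
        add(f"recovered angular velocity (deg/ms), {label}",
            angular_velocity(angles), omega, 0.01)

    return checks
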