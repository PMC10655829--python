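"""Middle-leg rowing-force equations, direct and indirect.

Two routes lead to the horizontal rowing force of one middle leg:

* **direct** — a force transducer hooked between femur and tibia measures
  ``F_MLBAP(t)``; modelling the leg as a rigid beam with a constant moment
  gives the tip force ``F_MLDir = (L / L_ML) * F_MLBAP``.
* **indirect** — high-speed video yields the body's peak acceleration ``a``;
  Newton gives the whole-body propellant force ``F_PropImg = m * a``, of
  which an empirical 70% is attributed to the two middle legs rowing in
  phase: ``2 * F_MLIndir = 0.7 * F_PropImg``.

All forces are carried in μN, masses in mg and accelerations in m/s^2;
this triple makes ``F = m a`` coefficient-free (1 mg·m/s^2 = 1 μN).
Rounding to published precision happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .kinematics import StrokeEvents, arrival_time, detect_onset

__all__ = [
    "BodyGeometry",
    "ForceTrace",
    "ForceResult",
    "tip_force_from_hook",
    "propellant_force",
    "middle_leg_from_propellant",
    "per_unit_length",
    "resultant_force",
    "peak_force",
]


@dataclass(frozen=True)
class BodyGeometry:
    """Body mass and middle-leg geometry.

    ``L_mm`` is the distance from the body to the femur-tibia hook point and
    ``L_ML_mm`` the full middle-leg length; the study's insects have a full
    leg over twice the hook distance, and the default ratio 0.44 is the one
    implied by the published mean hook and tip forces.  The leg-water contact
    length (default 11.0 mm) normalises forces per unit length.
    """

    mass_mg: float = 35.9
    L_mm: float = 11.0
    L_ML_mm: float = 25.0
    contact_length_mm: float = 11.0

    def __post_init__(self) -> None:
        if not self.mass_mg > 0:
            raise ConfigError(f"mass must be positive, got {self.mass_mg} mg")
        if not 0 < self.L_mm < self.L_ML_mm:
            raise ConfigError(
                f"need 0 < L ({self.L_mm}) < L_ML ({self.L_ML_mm})"
            )
        if not self.contact_length_mm > 0:
            raise ConfigError("contact length must be positive")

    @property
    def hook_ratio(self) -> float:
        """L / L_ML, the moment-arm ratio mapping hook force to tip force."""
        return self.L_mm / self.L_ML_mm


@dataclass
class ForceTrace:
    """Uniformly sampled force-transducer trace in μN."""

    t_ms: np.ndarray
    force_uN: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.force_uN = np.asarray(self.force_uN, dtype=float)
        if len(self.t_ms) != len(self.force_uN):
            raise ConfigError("t_ms and force_uN must have equal length")
        if not self.fs_hz > 0:
            raise ConfigError(f"fs_hz must be positive, got {self.fs_hz}")
        if not np.all(np.isfinite(self.force_uN)):
            raise ConfigError("force trace contains non-finite values")
        if len(self.t_ms) >= 2:
            dt = np.diff(self.t_ms)
            if np.ptp(dt) > 1e-9 * dt[0]:
                raise ConfigError("force trace must be uniformly sampled")

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass
class ForceResult:
    """The four headline forces plus derived per-length and resultant values.

    Fields are ``None`` when the corresponding route was not run (a direct
    trial carries no propellant force and vice versa).
    """

    f_mlbap_uN: float | None = None
    f_mldir_uN: float | None = None
    f_prop_uN: float | None = None
    f_mlindir_uN: float | None = None
    per_length_uN_mm: float | None = None
    resultant_uN: float | None = None

    def __post_init__(self) -> None:
        if (
            self.f_mlbap_uN is not None
            and self.f_mldir_uN is not None
            and self.f_mldir_uN > self.f_mlbap_uN
        ):
            raise ConfigError("tip force cannot exceed hook force (L < L_ML)")

    def as_dict(self) -> dict[str, float | None]:
        return dict(vars(self))


def tip_force_from_hook(f_mlbap_uN: float, geom: BodyGeometry) -> float:
    """Tip rowing force from the hook-point measurement (rigid-beam moment).

    ``F_MLDir = (L / L_ML) * F_MLBAP``; strictly less than the hook force
    because the hook sits inboard of the tip.
    """
    return geom.hook_ratio * f_mlbap_uN


def propellant_force(mass_mg: float, accel_ms2: float) -> float:
    """Whole-body propellant force ``F = m a`` in μN (mg x m/s^2 = μN)."""
    if not mass_mg > 0:
        raise ConfigError(f"mass must be positive, got {mass_mg} mg")
    return mass_mg * accel_ms2


def middle_leg_from_propellant(f_prop_uN: float, apportionment: float = 0.7,
                               n_legs: int = 2) -> float:
    """Single-middle-leg force from the whole-body propellant force.

    An empirical ``apportionment`` fraction (default 70%) of the propellant
    force is generated by the ``n_legs`` middle legs rowing simultaneously.
    """
    if not 0 < apportionment <= 1:
        raise ConfigError(f"apportionment must be in (0, 1], got {apportionment}")
    if n_legs < 1:
        raise ConfigError(f"n_legs must be >= 1, got {n_legs}")
    return apportionment * f_prop_uN / n_legs


def per_unit_length(f_uN: float, contact_length_mm: float = 11.0) -> float:
    """Force per unit leg-water contact length, μN/mm."""
    if not contact_length_mm > 0:
        raise ConfigError(
            f"contact length must be positive, got {contact_length_mm} mm"
        )
    return f_uN / contact_length_mm


def resultant_force(f_horizontal_uN: float, vertical_factor: float = 1.2) -> float:
    """Resultant rowing force from the horizontal component.

    The vertical force component measured by image analysis makes the
    resultant a fixed factor (default 1.2) larger than the horizontal force;
    a factor below 1 is impossible since a vertical component can only grow
    the resultant.
    """
    if vertical_factor < 1.0:
        raise ConfigError(
            f"vertical factor must be >= 1, got {vertical_factor}"
        )
    return f_horizontal_uN * vertical_factor


def peak_force(trace: ForceTrace, baseline_ms: float, k_sigma: float = 3.0,
               sustain_pts: int = 3) -> tuple[float, StrokeEvents]:
    """Peak force of a transducer trace and its arrival time from onset."""
    onset = detect_onset(trace.t_ms, trace.force_uN, baseline_ms,
                         k_sigma=k_sigma, sustain_pts=sustain_pts)
    events = arrival_time(trace.t_ms, trace.force_uN, onset)
    return events.peak_value, events
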