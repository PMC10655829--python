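"""Energy bookkeeping and study-level summary statistics.

The gap between the direct and indirect middle-leg force estimates is read as
an energy leak: the energy a rowing leg generates (``E_l``) splits into the
net propellant energy (``E_p``) plus losses to capillary-wave creation
(``E_c``), viscoelastic surface deformation (``E_v``), leg-water drag
(``E_d``), leg bending (``E_b``) and air resistance (``E_a``):

    E_p = E_l - (E_c + E_v + E_d + E_b + E_a)

No term-level physics is available for the losses, so the identity is exposed
as an accounting ledger, and the force-based loss fraction
``1 - F_MLIndir / F_MLDir`` serves as its quantitative proxy ("about half the
propellant energy was lost").  The module also pools per-trial maxima into
mean ± SD records mirroring the published summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "SYMBOLS",
    "EnergyBudget",
    "SummaryStat",
    "TrialResult",
    "StudySummary",
    "propellant_energy",
    "loss_fraction",
    "summarize",
    "build_summary",
]

# canonical symbols of the study's summary table, in its printed order
SYMBOLS = (
    "F_MLBAP",       # hook-point rowing force, direct (μN)
    "F_MLDir",       # tip rowing force, direct (μN)
    "t_maxF_Dir",    # maximum-force arrival time, direct (ms)
    "omega_ML_Dir",  # leg angular velocity, direct (deg/ms)
    "a_Prop_Img",    # peak propellant acceleration (m/s^2)
    "F_Prop_Img",    # whole-body propellant force (μN)
    "F_MLIndir",     # middle-leg rowing force, indirect (μN)
    "t_maxF_Indir",  # maximum-force arrival time, indirect (ms)
    "omega_ML_Indir",  # leg angular velocity, indirect (deg/ms)
    "v_max_Indir",   # maximum body speed (mm/s)
)

_LOSS_TERMS = ("E_c", "E_v", "E_d", "E_b", "E_a")


@dataclass
class EnergyBudget:
    """Energy ledger for one stroke, all terms in the same unit (e.g. μJ)."""

    E_l: float
    E_c: float = 0.0
    E_v: float = 0.0
    E_d: float = 0.0
    E_b: float = 0.0
    E_a: float = 0.0
    E_p: float | None = None
    deficit: bool = False

    def __post_init__(self) -> None:
        for name in _LOSS_TERMS:
            if getattr(self, name) < 0:
                raise ConfigError(f"loss term {name} must be nonnegative")

    @property
    def total_loss(self) -> float:
        return sum(getattr(self, name) for name in _LOSS_TERMS)


def propellant_energy(budget: EnergyBudget) -> EnergyBudget:
    """Complete the ledger: ``E_p = E_l - sum(losses)``.

    Sets ``deficit`` when the recorded losses exceed the leg energy (a sign of
    inconsistent inputs; the identity is still honoured).
    """
    budget.E_p = budget.E_l - budget.total_loss
    budget.deficit = budget.E_p < 0
    return budget


def loss_fraction(f_mldir_uN: float, f_mlindir_uN: float) -> float:
    """Fraction of the directly measured force missing from the indirect one.

    ``1 - F_MLIndir / F_MLDir`` in [0, 1); with the published means 955 and
    493 μN this is 0.484 — "about half".
    """
    if not f_mldir_uN > 0:
        raise ConfigError("direct force must be positive")
    if f_mlindir_uN > f_mldir_uN:
        raise ConfigError("indirect force cannot exceed the direct force")
    if f_mlindir_uN < 0:
        raise ConfigError("indirect force must be nonnegative")
    return 1.0 - f_mlindir_uN / f_mldir_uN


@dataclass(frozen=True)
class SummaryStat:
    """(n, mean, sample SD); SD is None for a single observation."""

    n: int
    mean: float
    sd: float | None


def summarize(values: Sequence[float]) -> SummaryStat:
    """Mean and sample SD (n-1 denominator) of a collection of trial values.

    The n-1 convention is pinned by the published insect weights: the six
    printed masses give 35.9 ± 3.5 mg only with the sample SD.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ConfigError("cannot summarize an empty collection")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return SummaryStat(n=int(arr.size), mean=mean, sd=sd)


@dataclass(frozen=True)
class TrialResult:
    """Per-trial maxima keyed by canonical symbol, tagged with the individual."""

    individual: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(SYMBOLS)
        if unknown:
            raise ConfigError(f"unknown symbols in trial: {sorted(unknown)}")


@dataclass
class StudySummary:
    """Pooled mean ± SD per symbol, mirroring the published summary table."""

    stats: dict[str, SummaryStat]
    pooling: str

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"symbol": sym, "n": st.n, "mean": st.mean, "sd": st.sd}
            for sym, st in self.stats.items()
        ]
        return pd.DataFrame(rows, columns=["symbol", "n", "mean", "sd"])


def build_summary(trials: Iterable[TrialResult],
                  pooling: str = "pooled") -> StudySummary:
    """Aggregate trial results into per-symbol mean ± SD records.

    ``pooled`` treats every trial as one observation; ``per_individual``
    first averages within each individual and then summarizes across the
    individual means (the two candidate conventions for a small-N study).
    """
    trials = list(trials)
    if not trials:
        raise ConfigError("need at least one trial")
    if pooling not in ("pooled", "per_individual"):
        raise ConfigError(f"unknown pooling mode {pooling!r}")

    stats: dict[str, SummaryStat] = {}
    for sym in SYMBOLS:
        if pooling == "pooled":
            vals = [t.values[sym] for t in trials if sym in t.values]
        else:
            by_ind: dict[str, list[float]] = {}
            for t in trials:
                if sym in t.values:
                    by_ind.setdefault(t.individual, []).append(t.values[sym])
            vals = [float(np.mean(v)) for v in by_ind.values()]
        if vals:
            stats[sym] = summarize(vals)
    if not stats:
        raise ConfigError("no recognised symbols in any trial")
    return StudySummary(stats=stats, pooling=pooling)
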