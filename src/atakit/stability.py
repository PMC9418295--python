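"""Resting vs operating stability: residual activity, inactivation kinetics.

An enzyme's *resting* (storage) stability is measured by incubating it in
buffer with its PLP cofactor only; *operating* stability adds an excess amine
donor and a ketone acceptor (default: 200 mM beta-alanine, 20 mM
cyclohexanone), which drives much of the enzyme into the fragile PMP state
where cofactor loss and denaturation are faster.  Residual activity at each
sampled time is expressed relative to the activity of the first sample
(taken after ~1 min of incubation), and first-order inactivation
``residual(t) = 100·exp(−k·t)`` is fitted on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AtakitError, InsufficientDataError


@dataclass(frozen=True)
class ConditionLabel:
    """Incubation condition of a stability time course."""

    mode: str  # "resting" or "operating"
    temperature_C: float = 40.0
    plp_mM: float = 0.1
    co_solvent: tuple[str, float] | None = None  # (name, % v/v)
    donor: tuple[str, float] | None = None  # (name, mM); operating only
    acceptor: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("resting", "operating"):
            raise AtakitError("mode must be 'resting' or 'operating'")
        if self.mode == "operating":
            donor = self.donor or ("beta-alanine", 200.0)
            acceptor = self.acceptor or ("cyclohexanone", 20.0)
            object.__setattr__(self, "donor", donor)
            object.__setattr__(self, "acceptor", acceptor)


@dataclass(frozen=True)
class StabilityTimeCourse:
    """Activity samples over incubation time, plus derived residual %.

    ``residual_pct`` is relative to the first (earliest) sample, which is by
    definition 100.
    """

    condition: ConditionLabel
    time_h: np.ndarray
    activity: np.ndarray  # raw volumetric activities, U/mL
    residual_pct: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "activity", a)
        if t.shape != a.shape or t.ndim != 1:
            raise AtakitError("time and activity must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise AtakitError("times must be strictly increasing")
        if self.residual_pct is None:
            if len(t) < 2:
                raise InsufficientDataError("a stability course needs >=2 samples")
            if not a[0] > 0:
                raise AtakitError("initial activity must be positive to define residuals")
            object.__setattr__(self, "residual_pct", 100.0 * a / a[0])
        else:
            object.__setattr__(self, "residual_pct", np.asarray(self.residual_pct, dtype=float))

    def __len__(self) -> int:
        return len(self.time_h)


def residual_activity(
    condition: ConditionLabel, time_h: Sequence[float], activity: Sequence[float]
) -> StabilityTimeCourse:
    """Build a course with residual(t) = 100·A(t)/A(t_first).

    The reference is the first *sample* (the ~1 min "initial" measurement),
    not an extrapolation to t = 0.  Residuals are invariant under rescaling
    all raw activities by a common positive factor.
    """
    return StabilityTimeCourse(condition, np.asarray(time_h), np.asarray(activity))


@dataclass(frozen=True)
class InactivationFit:
    """First-order inactivation rate and half-life."""

    rate_per_h: float
    half_life_h: float  # inf for a non-decaying course
    r_squared: float
    nondecaying: bool = False


def fit_inactivation(course: StabilityTimeCourse) -> InactivationFit:
    """Least-squares fit of ln(residual) vs time; k = −slope.

    A non-decaying course (fitted slope >= 0) reports k = 0 with infinite
    half-life and the ``nondecaying`` flag, rather than a negative rate.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 samples.
    AtakitError
        Residuals outside (0, 100] — log-linear fitting is undefined at 0.
    """
    if len(course) < 3:
        raise InsufficientDataError("inactivation fit needs >=3 samples")
    r = course.residual_pct
    if np.any(r <= 0):
        raise AtakitError("residuals must be positive for a log-linear fit")
    res = stats.linregress(course.time_h, np.log(r))
    r2 = 1.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    k = -float(res.slope)
    if k <= 0:
        return InactivationFit(0.0, math.inf, r2, nondecaying=True)
    return InactivationFit(k, math.log(2.0) / k, r2)


def residual_at(course: StabilityTimeCourse, time_h: float) -> float:
    """Residual % at a time point, linearly interpolated between samples.

    No extrapolation: times outside the sampled range raise.
    """
    t = course.time_h
    if not (t[0] <= time_h <= t[-1]):
        raise AtakitError(
            f"time {time_h} h outside sampled range [{t[0]}, {t[-1]}] h; no extrapolation"
        )
    return float(np.interp(time_h, t, course.residual_pct))


@dataclass(frozen=True)
class ConditionComparison:
    """Resting vs operating residual activity at one time point."""

    time_h: float
    resting_pct: float
    operating_pct: float
    difference_pct: float  # resting − operating


def compare_conditions(
    resting: StabilityTimeCourse, operating: StabilityTimeCourse, time_h: float
) -> ConditionComparison:
    """Paired resting/operating summary at ``time_h`` (default workflow: 8 h).

    Both courses must share mode-appropriate labels and the same incubation
    temperature; the comparison quantifies how much stability is lost when
    substrates are present.
    """
    if resting.condition.mode != "resting" or operating.condition.mode != "operating":
        raise AtakitError("expected one resting and one operating course, in that order")
    if resting.condition.temperature_C != operating.condition.temperature_C:
        raise AtakitError("courses must share the incubation temperature")
    rs = residual_at(resting, time_h)
    os_ = residual_at(operating, time_h)
    return ConditionComparison(time_h, rs, os_, rs - os_)


def solvent_panel(
    courses: Mapping[tuple[str, float], StabilityTimeCourse],
    reference: StabilityTimeCourse,
    time_h: float,
) -> dict[tuple[str, float], float]:
    """Co-solvent tolerance relative to a no-solvent reference.

    For each ``(solvent name, % v/v)`` course, returns
    ``100 · residual(co-solvent) / residual(reference)`` at the matching time.
    """
    ref = residual_at(reference, time_h)
    if not ref > 0:
        raise AtakitError("reference residual must be positive")
    return {key: 100.0 * residual_at(c, time_h) / ref for key, c in courses.items()}
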