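"""Photometric assay traces -> volumetric, specific and relative activities.

Two coupled photometric assays are supported:

* **acetophenone assay** — acetophenone formed from 1-phenylethylamine is
  followed at 245 nm; volumetric activity (U/mL) = slope[ΔAbs/min] * 60 / 5.23.
* **AlaDH/XTT assay** — alanine formed from pyruvate is coupled through
  alanine dehydrogenase, NAD+ and a tetrazolium dye; activity (U/mL) =
  slope * 60 / 12.64.

The divisors 5.23 and 12.64 are instrument calibration constants bundling
extinction coefficient and path length; they are used verbatim, not
re-derived.  One unit is 1 µmol product (acetophenone, or formazane dye)
per minute.  Specific activities below 4 mU/mg are flagged "not detectable"
(ND), the assay's empirical detection floor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AtakitError, InsufficientDataError

#: specific-activity detection floor, mU/mg
ND_FLOOR_MU_PER_MG = 4.0

TRACE_LABELS = ("reaction", "blank_no_amine", "blank_no_enzyme", "blank_no_acceptor")


@dataclass(frozen=True)
class AssayConstants:
    """Calibration of one photometric assay.

    ``factor`` converts a blank-corrected slope in ΔAbs/min into U/mL via
    ``slope * 60 / factor``; ``blank_rule`` names the control whose slope is
    subtracted from the reaction slope.
    """

    name: str
    factor: float
    blank_rule: str

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise AtakitError("assay factor must be positive")


ACETOPHENONE = AssayConstants("acetophenone", 5.23, blank_rule="blank_no_amine")
ALADH = AssayConstants("aladh", 12.64, blank_rule="blank_no_enzyme")
ASSAYS: Mapping[str, AssayConstants] = {"acetophenone": ACETOPHENONE, "aladh": ALADH}


@dataclass(frozen=True)
class KineticTrace:
    """One absorbance time series from a plate reader well."""

    time_min: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float = 245.0
    label: str = "reaction"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "absorbance", a)
        if t.shape != a.shape or t.ndim != 1:
            raise AtakitError("time and absorbance must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise AtakitError("time points must be strictly increasing")
        if self.label not in TRACE_LABELS:
            raise AtakitError(f"label must be one of {TRACE_LABELS}")

    def __len__(self) -> int:
        return len(self.time_min)


@dataclass(frozen=True)
class SlopeFit:
    slope: float  # ΔAbs/min
    stderr: float
    intercept: float
    r_squared: float
    n_points: int


def fit_slope(
    trace: KineticTrace,
    window_min: tuple[float, float] | None = None,
    auto_trim: bool = False,
    r2_threshold: float = 0.98,
) -> SlopeFit:
    """Ordinary least-squares slope of absorbance vs time.

    Parameters
    ----------
    window_min:
        ``(start, end)`` in minutes; default is the full trace.
    auto_trim:
        Drop trailing points one at a time (down to 3) while R² is below
        ``r2_threshold``, to exclude substrate-depletion curvature at high
        activity.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 points fall in the window.
    """
    t, a = trace.time_min, trace.absorbance
    if window_min is not None:
        lo, hi = window_min
        mask = (t >= lo) & (t <= hi)
        t, a = t[mask], a[mask]
    if len(t) < 3:
        raise InsufficientDataError(f"slope fit needs >=3 points, got {len(t)}")

    def _fit(tt: np.ndarray, aa: np.ndarray) -> SlopeFit:
        res = stats.linregress(tt, aa)
        # a perfectly flat trace has r undefined; treat as exact fit
        r2 = 1.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
        se = 0.0 if np.isnan(res.stderr) else float(res.stderr)
        return SlopeFit(float(res.slope), se, float(res.intercept), r2, len(tt))

    fit = _fit(t, a)
    while auto_trim and fit.r_squared < r2_threshold and len(t) > 3:
        t, a = t[:-1], a[:-1]
        fit = _fit(t, a)
    return fit


def blank_correct(reaction_slope: float, control_slope: float) -> float:
    """Subtract a control slope; clip negative results to 0 with a warning.

    A corrected slope below zero means the control consumed signal faster
    than the reaction — reported as zero activity, never negative.
    """
    corrected = reaction_slope - control_slope
    if corrected < 0:
        warnings.warn(
            f"blank-corrected slope {corrected:.4g} ΔAbs/min is negative; clipping to 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    return corrected


def activity_from_slope(slope: float, constants: AssayConstants) -> float:
    """Volumetric activity U/mL = slope * 60 / factor.

    Raises on a negative slope: blank-correct first.
    """
    if slope < 0:
        raise AtakitError("slope must be non-negative; apply blank_correct first")
    return slope * 60.0 / constants.factor


@dataclass(frozen=True)
class ActivityResult:
    """Volumetric + specific activity with the not-detectable flag.

    ``nd`` is True exactly when the specific activity lies below the
    4 mU/mg floor.  ``mean``/``sd`` summarize replicates when present.
    """

    volumetric_U_per_mL: float
    specific_mU_per_mg: float
    nd: bool
    protein_conc_mg_per_mL: float
    replicate_mean: float | None = None
    replicate_sd: float | None = None

    def __post_init__(self) -> None:
        if self.nd != (self.specific_mU_per_mg < ND_FLOOR_MU_PER_MG):
            raise AtakitError("ND flag inconsistent with the 4 mU/mg floor")


def specific_activity(volumetric_U_per_mL: float, protein_conc_mg_per_mL: float) -> ActivityResult:
    """Specific activity mU/mg = 1000 * (U/mL) / (mg/mL), with ND flag."""
    if protein_conc_mg_per_mL <= 0:
        raise AtakitError("protein concentration must be positive")
    spec = 1000.0 * volumetric_U_per_mL / protein_conc_mg_per_mL
    return ActivityResult(
        volumetric_U_per_mL=volumetric_U_per_mL,
        specific_mU_per_mg=spec,
        nd=spec < ND_FLOOR_MU_PER_MG,
        protein_conc_mg_per_mL=protein_conc_mg_per_mL,
    )


def replicate_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean ± sample standard deviation over replicate measurements (n >= 3
    mirrors triplicate plate-reader practice, but n >= 2 is accepted)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InsufficientDataError("replicate summary needs >=2 values")
    return float(np.mean(v)), float(np.std(v, ddof=1))


@dataclass(frozen=True)
class RelativeActivityTable:
    """Specific activities expressed as percent of a reference substrate."""

    reference_substrate: str
    percent: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.percent[self.reference_substrate] != 100.0:
            raise AtakitError("reference substrate must be exactly 100%")
        if any(v < 0 for v in self.percent.values()):
            raise AtakitError("relative activities must be non-negative")


def relative_table(
    specifics: Mapping[str, float], reference_substrate: str
) -> RelativeActivityTable:
    """Percent = 100 * value / reference value; the reference is exactly 100.

    Raises if the reference substrate is missing or non-positive (an ND
    reference makes every ratio meaningless).
    """
    if reference_substrate not in specifics:
        raise AtakitError(f"reference substrate {reference_substrate!r} not in table")
    ref = specifics[reference_substrate]
    if not ref > 0:
        raise AtakitError("reference specific activity must be positive (not 0/ND)")
    percent = {s: 100.0 * v / ref for s, v in specifics.items()}
    percent[reference_substrate] = 100.0
    return RelativeActivityTable(reference_substrate, percent)


def activity_from_trace(
    trace: KineticTrace,
    constants: AssayConstants,
    control: KineticTrace | None = None,
    protein_conc_mg_per_mL: float | None = None,
    window_min: tuple[float, float] | None = None,
) -> ActivityResult | float:
    """Convenience pipeline: fit slope, blank-correct, convert to activity.

    Returns an :class:`ActivityResult` when a protein concentration is given,
    else the volumetric activity in U/mL.
    """
    slope = fit_slope(trace, window_min).slope
    if control is not None:
        slope = blank_correct(slope, fit_slope(control, window_min).slope)
    else:
        slope = max(slope, 0.0)
    vol = activity_from_slope(slope, constants)
    if protein_conc_mg_per_mL is None:
        return vol
    return specific_activity(vol, protein_conc_mg_per_mL)
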