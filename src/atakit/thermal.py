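"""Thermal unfolding curves and melting-temperature (Tm) extraction.

Differential scanning fluorimetry (nanoDSF) reports an intrinsic-fluorescence
ratio (350 nm / 330 nm) while the sample is heated, typically 20–95 °C at
0.5 °C/min.  For a two-state unfolder the ratio traces a sigmoid whose
midpoint is the melting temperature; instruments report Tm as the peak of
the first derivative of the ratio signal.  This module implements that
derivative-peak extractor (local-polynomial smoothing, central differences,
parabolic sub-grid refinement) plus the two-state van't Hoff model used to
simulate such curves, and offers a direct sigmoid fit as an alternative.

Temperatures are degrees Celsius at every interface; the van't Hoff model
works in kelvin internally (0 °C = 273.15 K exactly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .errors import AtakitError, ConfigurationError, InsufficientDataError, NoTransitionError

KELVIN_OFFSET = 273.15
#: gas constant, kJ/(mol·K)
R_KJ = 8.31446261815324e-3


def fraction_unfolded(temp_C: np.ndarray | float, midpoint_C: float, dH_kJ_mol: float) -> np.ndarray | float:
    """Two-state van't Hoff fraction unfolded.

    ``f(T) = 1 / (1 + exp[(ΔH/R)·(1/T − 1/Tmid)])`` with T in kelvin, so that
    f(Tmid) = 1/2 exactly and larger ΔH gives a sharper transition.
    """
    if dH_kJ_mol <= 0:
        raise ConfigurationError("van't Hoff enthalpy must be positive")
    T = np.asarray(temp_C, dtype=float) + KELVIN_OFFSET
    Tm = midpoint_C + KELVIN_OFFSET
    return 1.0 / (1.0 + np.exp((dH_kJ_mol / R_KJ) * (1.0 / T - 1.0 / Tm)))


@dataclass(frozen=True)
class MeltParams:
    """Parameters of a simulated two-state melting curve.

    Baselines are linear in °C: ``value = intercept + slope · T``; the folded
    baseline applies before the transition, the unfolded one after.  Real
    nanoDSF ratio baselines drift mildly, hence nonzero default slopes; set
    them to 0 for analytically flat baselines.
    """

    midpoint_C: float
    dH_kJ_mol: float = 400.0
    folded_intercept: float = 0.80
    folded_slope: float = 2.0e-4
    unfolded_intercept: float = 0.95
    unfolded_slope: float = 4.0e-4

    def signal(self, temp_C: np.ndarray) -> np.ndarray:
        T = np.asarray(temp_C, dtype=float)
        f = fraction_unfolded(T, self.midpoint_C, self.dH_kJ_mol)
        folded = self.folded_intercept + self.folded_slope * T
        unfolded = self.unfolded_intercept + self.unfolded_slope * T
        return (1.0 - f) * folded + f * unfolded


@dataclass(frozen=True)
class MeltingCurve:
    """Fluorescence ratio vs temperature on an increasing grid."""

    temp_C: np.ndarray
    ratio: np.ndarray
    heating_rate_C_min: float = 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.temp_C, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        object.__setattr__(self, "temp_C", t)
        object.__setattr__(self, "ratio", r)
        if t.shape != r.shape or t.ndim != 1:
            raise AtakitError("temperature and ratio must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise AtakitError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temp_C)


@dataclass(frozen=True)
class TmResult:
    """Extracted melting temperature."""

    tm_C: float
    peak_height: float  # derivative amplitude at the peak, ratio units/°C
    method: str = "derivative_peak"
    replicate_mean: float | None = None
    replicate_sd: float | None = None


def _smooth(ratio: np.ndarray, step_C: float, window_C: float, polyorder: int) -> np.ndarray:
    window = max(int(round(window_C / step_C)) | 1, polyorder + 2)
    if window % 2 == 0:
        window += 1
    window = min(window, len(ratio) if len(ratio) % 2 else len(ratio) - 1)
    if window <= polyorder:
        return ratio
    return savgol_filter(ratio, window, polyorder)


def compute_tm(
    curve: MeltingCurve,
    smoothing_window_C: float = 2.0,
    polyorder: int = 2,
    derivative_space: str = "reciprocal",
) -> TmResult:
    """Tm as the temperature of the first-derivative maximum.

    The ratio signal is smoothed with a local polynomial (Savitzky–Golay,
    window ≈ 2 °C, order 2 by default), differentiated by central differences,
    and the global derivative maximum is refined below grid resolution by
    fitting a parabola through the peak and its two neighbours.  With several
    local maxima the global one wins; exact ties go to the lower temperature
    (single-transition assumption).

    By default the derivative is taken with respect to reciprocal absolute
    temperature (``derivative_space="reciprocal"``), in which a two-state
    van't Hoff transition is exactly symmetric, so the peak sits at the true
    midpoint even for broad (low-enthalpy) transitions.  For sharp
    transitions this coincides with the plain temperature derivative
    (``derivative_space="temperature"``), the convention scanning
    fluorimeters print.

    Raises
    ------
    InsufficientDataError
        Fewer than 20 grid points.
    NoTransitionError
        The derivative maximum sits on the grid boundary (no interior peak —
        the transition is outside, or not in, the scanned range).
    """
    if len(curve) < 20:
        raise InsufficientDataError("Tm extraction needs >=20 grid points")
    if derivative_space not in ("reciprocal", "temperature"):
        raise AtakitError("derivative_space must be 'reciprocal' or 'temperature'")
    t = curve.temp_C
    step = float(np.median(np.diff(t)))
    smoothed = _smooth(curve.ratio, step, smoothing_window_C, polyorder)
    deriv = np.gradient(smoothed, t)
    if derivative_space == "reciprocal":
        # dR/d(1/T) = −T²·dR/dT; magnitude re-weighted so the van't Hoff
        # sigmoid peaks exactly at its midpoint
        deriv = deriv * (t + KELVIN_OFFSET) ** 2
    peak = int(np.argmax(deriv))  # argmax takes the first (lowest-T) of ties
    if peak == 0 or peak == len(t) - 1:
        raise NoTransitionError("derivative maximum at grid boundary; no interior transition")
    # parabolic sub-grid refinement: least-squares quadratic over a ~±2.5 °C
    # window around the discrete peak (≈ a quarter of a typical transition
    # width; falls back to the 3 nearest points), vertex clipped to the window
    half = max(1, int(round(2.5 / step)))
    lo, hi = max(peak - half, 0), min(peak + half, len(t) - 1)
    tw, yw = t[lo : hi + 1], deriv[lo : hi + 1]
    a, b, _c = np.polyfit(tw - t[peak], yw, 2)
    if a < 0:
        offset = float(np.clip(-b / (2.0 * a), -half * step, half * step))
    else:  # degenerate curvature: keep the grid maximum
        offset = 0.0
    tm = t[peak] + offset
    return TmResult(tm_C=float(tm), peak_height=float(deriv[peak]))


def _two_state_model(T, midpoint, dH, fi, fs, ui, us):
    f = 1.0 / (1.0 + np.exp((dH / R_KJ) * (1.0 / (T + KELVIN_OFFSET) - 1.0 / (midpoint + KELVIN_OFFSET))))
    return (1.0 - f) * (fi + fs * T) + f * (ui + us * T)


def fit_tm_sigmoid(curve: MeltingCurve) -> TmResult:
    """Alternative Tm: direct two-state fit with linear baselines.

    Fits the van't Hoff sigmoid (plus folded/unfolded linear baselines) to
    the raw ratio signal and reports the fitted midpoint.  More robust than
    the derivative peak on very noisy curves, but model-bound.
    """
    if len(curve) < 20:
        raise InsufficientDataError("Tm fit needs >=20 grid points")
    t, r = curve.temp_C, curve.ratio
    guess_mid = float(t[np.argmax(np.gradient(savgol_filter(r, 9, 2), t))])
    p0 = [guess_mid, 400.0, r[0], 0.0, r[-1], 0.0]
    try:
        popt, _ = curve_fit(_two_state_model, t, r, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise NoTransitionError(f"sigmoid fit did not converge: {exc}") from exc
    mid = float(popt[0])
    if not (t[0] < mid < t[-1]):
        raise NoTransitionError("fitted midpoint outside the scanned range")
    dH = abs(float(popt[1]))
    # derivative amplitude at the midpoint for comparability with the peak method
    height = dH / R_KJ / (4.0 * (mid + KELVIN_OFFSET) ** 2) * abs(popt[4] + popt[5] * mid - popt[2] - popt[3] * mid)
    return TmResult(tm_C=mid, peak_height=height, method="sigmoid_fit")


def tm_replicates(curves: Sequence[MeltingCurve], **kwargs) -> TmResult:
    """Tm over replicate curves: per-curve extraction, mean ± sample sd."""
    if not curves:
        raise InsufficientDataError("no curves given")
    tms = [compute_tm(c, **kwargs).tm_C for c in curves]
    base = compute_tm(curves[0], **kwargs)
    sd = float(np.std(tms, ddof=1)) if len(tms) > 1 else None
    return TmResult(
        tm_C=float(np.mean(tms)),
        peak_height=base.peak_height,
        replicate_mean=float(np.mean(tms)),
        replicate_sd=sd,
    )
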