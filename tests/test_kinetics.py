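"""Slope fitting, blank correction, unit conversion, relative activities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import atakit as ak
from atakit.kinetics import (
    ACETOPHENONE,
    ALADH,
    KineticTrace,
    activity_from_slope,
    activity_from_trace,
    blank_correct,
    fit_slope,
    relative_table,
    replicate_summary,
    specific_activity,
)
from atakit.synthetic import gen_trace


def test_exact_slope_on_collinear_points():
    tr = KineticTrace(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.1, 0.2]))
    fit = fit_slope(tr)
    assert fit.slope == pytest.approx(0.2, abs=1e-12)
    assert fit.stderr == pytest.approx(0.0, abs=1e-12)


def test_flat_trace_slope_zero():
    tr = KineticTrace(np.linspace(0, 10, 21), np.full(21, 0.3))
    assert fit_slope(tr).slope == pytest.approx(0.0, abs=1e-15)


def test_too_few_points_rejected():
    tr = KineticTrace(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.1, 0.2]))
    with pytest.raises(ak.InsufficientDataError):
        fit_slope(tr, window_min=(0.0, 1.0))


def test_window_restricts_fit():
    t = np.linspace(0, 10, 21)
    a = np.where(t <= 5, 0.1 * t, 0.5)  # linear then saturated
    tr = KineticTrace(t, a)
    assert fit_slope(tr, window_min=(0.0, 5.0)).slope == pytest.approx(0.1, abs=1e-12)
    assert fit_slope(tr).slope < 0.1


def test_auto_trim_recovers_initial_linear_range():
    # saturation after 6 min: trimming stops once the retained window is
    # linear enough, pulling the slope toward the true initial rate
    t = np.linspace(0, 10, 21)
    a = np.where(t <= 6, 0.05 * t, 0.3)
    trimmed = fit_slope(KineticTrace(t, a), auto_trim=True)
    full = fit_slope(KineticTrace(t, a))
    assert trimmed.n_points < full.n_points
    assert trimmed.r_squared >= 0.98
    assert abs(trimmed.slope - 0.05) < abs(full.slope - 0.05)
    assert trimmed.slope == pytest.approx(0.05, rel=0.1)


@pytest.mark.parametrize(
    "reaction,control,expected", [(0.25, 0.05, 0.20), (0.05, 0.05, 0.0)]
)
def test_blank_correction(reaction, control, expected):
    assert blank_correct(reaction, control) == pytest.approx(expected)


def test_negative_corrected_slope_clips_with_warning():
    with pytest.warns(UserWarning, match="negative"):
        assert blank_correct(0.03, 0.05) == 0.0


@pytest.mark.parametrize(
    "slope,constants,expected",
    [
        (0.0523, ACETOPHENONE, 0.600),  # slope*60/5.23
        (0.0, ACETOPHENONE, 0.0),
        (0.0, ALADH, 0.0),
        (0.2107, ALADH, 1.0001),  # slope*60/12.64
    ],
)
def test_activity_formula(slope, constants, expected):
    assert activity_from_slope(slope, constants) == pytest.approx(expected, abs=5e-4)


def test_negative_slope_rejected():
    with pytest.raises(ak.AtakitError):
        activity_from_slope(-0.01, ACETOPHENONE)


@given(s1=st.floats(0, 1), s2=st.floats(0, 1))
def test_activity_is_linear_and_monotone_in_slope(s1, s2):
    a1 = activity_from_slope(s1, ACETOPHENONE)
    a2 = activity_from_slope(s2, ACETOPHENONE)
    assert activity_from_slope(s1 + s2, ACETOPHENONE) == pytest.approx(a1 + a2, rel=1e-9)
    if s1 < s2:
        assert a1 <= a2


@pytest.mark.parametrize(
    "vol,conc,spec,nd",
    [
        (0.6, 0.5, 1200.0, False),  # high amine activity magnitude
        (0.001, 1.0, 1.0, True),  # below the 4 mU/mg floor
        (0.0, 1.0, 0.0, True),
    ],
)
def test_specific_activity_and_nd_floor(vol, conc, spec, nd):
    res = specific_activity(vol, conc)
    assert res.specific_mU_per_mg == pytest.approx(spec)
    assert res.nd is nd


def test_nonpositive_concentration_rejected():
    with pytest.raises(ak.AtakitError):
        specific_activity(0.5, 0.0)


def test_relative_table_reference_is_exactly_100():
    # alpha-ketoglutarate at 18.7 vs pyruvate 4680 -> 0.4%
    table = relative_table({"pyruvate": 4680.0, "alpha-ketoglutarate": 18.7}, "pyruvate")
    assert table.percent["pyruvate"] == 100.0
    assert table.percent["alpha-ketoglutarate"] == pytest.approx(0.4, abs=0.05)
    assert relative_table({"ref": 7.0}, "ref").percent == {"ref": 100.0}


def test_relative_table_errors():
    with pytest.raises(ak.AtakitError):
        relative_table({"a": 1.0}, "b")
    with pytest.raises(ak.AtakitError):
        relative_table({"a": 0.0}, "a")


@given(
    scale=st.floats(0.01, 100),
    values=st.dictionaries(
        st.sampled_from("abcdef"), st.floats(1.0, 1e4), min_size=2
    ),
)
def test_relative_table_scale_invariant(scale, values):
    ref = sorted(values)[0]
    base = relative_table(values, ref)
    scaled = relative_table({k: v * scale for k, v in values.items()}, ref)
    for k in values:
        assert scaled.percent[k] == pytest.approx(base.percent[k], rel=1e-9)


def test_replicate_summary_mean_sd():
    mean, sd = replicate_summary([1.0, 2.0, 3.0])
    assert mean == 2.0
    assert sd == pytest.approx(1.0)


def test_generator_round_trip_noiseless():
    """gen_trace -> fit_slope -> activity recovers planted activity <0.1%."""
    for assay in (ACETOPHENONE, ALADH):
        for planted in (0.01, 0.1, 1.0, 10.0):
            tr = gen_trace(planted, assay)
            got = activity_from_slope(fit_slope(tr).slope, assay)
            assert got == pytest.approx(planted, rel=1e-9)


def test_generator_round_trip_noisy_unbiased():
    """With plate-reader-scale noise the estimator is unbiased: mean over
    many seeds within 2 standard errors of the planted activity."""
    planted = 0.6
    est = [
        activity_from_slope(
            fit_slope(gen_trace(planted, ACETOPHENONE, noise_sd=0.002, seed=s)).slope,
            ACETOPHENONE,
        )
        for s in range(200)
    ]
    se = np.std(est, ddof=1) / np.sqrt(len(est))
    assert abs(np.mean(est) - planted) <= 2 * se


def test_activity_from_trace_pipeline():
    reaction = gen_trace(0.6, ACETOPHENONE, intercept=0.05)
    blank = gen_trace(0.05, ACETOPHENONE, intercept=0.02, label="blank_no_amine")
    res = activity_from_trace(reaction, ACETOPHENONE, blank, protein_conc_mg_per_mL=0.5)
    assert res.volumetric_U_per_mL == pytest.approx(0.55, rel=1e-9)
    assert res.specific_mU_per_mg == pytest.approx(1100.0, rel=1e-9)
    assert not res.nd
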