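"""Generators: determinism, planted-parameter recovery, round-trip I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import atakit as ak
from atakit import io
from atakit.synthetic import SimConfig, gen_alignment, gen_inactivation, gen_melting_curve, gen_trace

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- alignment
def test_same_seed_same_fasta_bytes(tmp_path):
    p1, p2 = tmp_path / "a1.fasta", tmp_path / "a2.fasta"
    ak.write_alignment(gen_alignment(SimConfig(seed=1)), p1)
    ak.write_alignment(gen_alignment(SimConfig(seed=1)), p2)
    assert p1.read_bytes() == p2.read_bytes()
    ak.write_alignment(gen_alignment(SimConfig(seed=2)), p2)
    assert p1.read_bytes() != p2.read_bytes()


@given(
    fps=st.dictionaries(
        st.sampled_from(["TA-3N5M", "s1", "s2", "s3"]),
        st.text(alphabet=AA, min_size=7, max_size=7),
        min_size=1,
    ).map(lambda d: {**d, "TA-3N5M": d.get("TA-3N5M", "MWYRGGN")}),
    seed=st.integers(0, 2**20),
)
def test_extraction_of_planting_is_identity(fps, seed):
    """extract_fingerprint inverts gen_alignment's planting exactly, for any
    planted fingerprints."""
    cfg = SimConfig(seed=seed, n_sequences=len(fps), planted_fingerprints=fps)
    aln = gen_alignment(cfg)
    pmap = ak.build_position_map(aln, "TA-3N5M", ak.default_anchors())
    for sid, planted in fps.items():
        assert str(ak.extract_fingerprint(aln, pmap, sid)) == planted.upper()


def test_two_identical_sequences_are_100_percent():
    fps = {"TA-3N5M": "MWYRGGN", "twin": "MWYRGGN"}
    cfg = SimConfig(seed=5, n_sequences=2, planted_fingerprints=fps, target_identity=1.0)
    aln = gen_alignment(cfg)
    m = ak.pairwise_identity(aln)
    assert m.value("TA-3N5M", "twin") == 100.0


@pytest.mark.parametrize("target", [0.35, 0.421, 0.60, 0.80])
def test_target_identity_is_realized(target):
    cfg = SimConfig(seed=7, target_identity=target)
    m = ak.pairwise_identity(gen_alignment(cfg))
    for sid in cfg.planted_fingerprints:
        if sid != "TA-3N5M":
            assert abs(m.value(sid, "TA-3N5M") - 100 * target) <= 2.0


def test_per_sequence_identity_targets():
    targets = {"TA-1": 0.421, "TA-9": 0.412, "TA-10": 0.391, "TA-5": 0.351}
    cfg = SimConfig(seed=13, target_identity=targets)
    m = ak.pairwise_identity(gen_alignment(cfg))
    for sid, t in targets.items():
        assert abs(m.value(sid, "TA-3N5M") - 100 * t) <= 0.5


def test_alignment_too_short_rejected():
    with pytest.raises(ak.ConfigurationError):
        gen_alignment(SimConfig(alignment_length=300))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"planted_fingerprints": {"TA-3N5M": "MWYRGG"}},  # wrong length
        {"planted_fingerprints": {"TA-3N5M": "MWYRGG-"}},  # gap letter
        {"trace_noise_sd": -0.1},
        {"inactivation_rate_per_h": -1.0},
        {"target_identity": 1.5},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ak.ConfigurationError):
        SimConfig(**kwargs)


def test_config_yaml_round_trip(tmp_path):
    cfg = SimConfig(seed=3, target_identity=0.4, melt_params=ak.MeltParams(midpoint_C=81.3))
    path = tmp_path / "sim.yaml"
    ak.save_config(cfg, path)
    assert ak.load_config(path) == cfg


# -------------------------------------------------------------------- trace
def test_default_grid_has_21_samples():
    tr = gen_trace(0.6, ak.ACETOPHENONE)
    assert len(tr) == 21
    assert tr.time_min[0] == 0.0
    assert tr.time_min[-1] == 10.0
    assert np.allclose(np.diff(tr.time_min), 0.5)


def test_noiseless_slope_inverts_activity_formula():
    # 0.6 U/mL with the acetophenone factor -> slope 0.6*5.23/60 = 0.0523
    tr = gen_trace(0.6, ak.ACETOPHENONE)
    assert ak.fit_slope(tr).slope == pytest.approx(0.0523, abs=1e-12)


def test_zero_activity_is_flat():
    tr = gen_trace(0.0, ak.ALADH)
    assert ak.fit_slope(tr).slope == pytest.approx(0.0, abs=1e-15)
    assert np.ptp(tr.absorbance) == 0.0


def test_negative_activity_rejected():
    with pytest.raises(ak.AtakitError):
        gen_trace(-0.1, ak.ACETOPHENONE)


def test_trace_round_trip(tmp_path):
    tr = gen_trace(0.8, ak.ALADH, noise_sd=0.002, seed=4)
    path = tmp_path / "trace.csv"
    io.write_trace(tr, path)
    back = io.read_trace(path)
    assert np.array_equal(back.time_min, tr.time_min)
    assert np.array_equal(back.absorbance, tr.absorbance)


# ------------------------------------------------------------ melting curve
def test_fraction_unfolded_is_half_at_midpoint():
    assert ak.fraction_unfolded(87.0, 87.0, 400.0) == pytest.approx(0.5, abs=1e-12)


def test_larger_enthalpy_narrows_transition():
    # width between f=0.25 and f=0.75, evaluated on the closed form
    t = np.linspace(60, 80, 4001)
    widths = []
    for dh in (200.0, 400.0, 600.0):
        f = ak.fraction_unfolded(t, 70.0, dh)
        widths.append(t[f >= 0.75][0] - t[f >= 0.25][0])
    assert widths[0] > widths[1] > widths[2]


def test_midpoint_outside_grid_rejected():
    with pytest.raises(ak.ConfigurationError):
        gen_melting_curve(ak.MeltParams(midpoint_C=10.0))


def test_melting_round_trip(tmp_path):
    curve = gen_melting_curve(ak.MeltParams(midpoint_C=70.0), noise_sd=0.001, seed=2)
    path = tmp_path / "melt.csv"
    io.write_melting_curve(curve, path)
    back = io.read_melting_curve(path)
    assert np.array_equal(back.temp_C, curve.temp_C)
    assert np.array_equal(back.ratio, curve.ratio)


def test_melting_determinism():
    a = gen_melting_curve(ak.MeltParams(midpoint_C=70.0), noise_sd=0.01, seed=9)
    b = gen_melting_curve(ak.MeltParams(midpoint_C=70.0), noise_sd=0.01, seed=9)
    assert np.array_equal(a.ratio, b.ratio)


# ------------------------------------------------------------- inactivation
def test_no_decay_at_rate_zero():
    course = gen_inactivation(0.0)
    assert np.all(course.residual_pct == 100.0)


def test_first_order_decay_value():
    # 100*exp(-0.1*8) = 44.93%
    course = gen_inactivation(0.1, schedule_h=(0.0, 4.0, 8.0))
    assert course.residual_pct[-1] == pytest.approx(100 * np.exp(-0.8), rel=1e-12)
    assert course.residual_pct[0] == 100.0


def test_planted_85_percent_at_20_hours():
    # rate chosen so that 15% is lost over 20 h
    rate = np.log(100 / 85) / 20
    course = gen_inactivation(rate, schedule_h=(0.0, 10.0, 20.0))
    assert course.residual_pct[-1] == pytest.approx(85.0, rel=1e-12)


def test_negative_rate_rejected():
    with pytest.raises(ak.AtakitError):
        gen_inactivation(-0.1)


def test_noisy_reference_sample_stays_100():
    course = gen_inactivation(0.2, noise_sd=3.0, seed=1)
    assert course.residual_pct[0] == 100.0


def test_stability_round_trip(tmp_path):
    course = gen_inactivation(0.15, noise_sd=1.0, seed=6)
    path = tmp_path / "decay.csv"
    io.write_stability(course, path)
    back = io.read_stability(path)
    assert np.array_equal(back.time_h, course.time_h)
    assert np.array_equal(back.residual_pct, course.residual_pct)
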