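"""Synthetic data with the statistical structure the analyses assume.

Every input the pipeline consumes can be generated here: reference-anchored
alignments with planted active-site fingerprints and controlled identity,
linear photometric assay traces obeying the activity formulas, two-state
van't Hoff melting curves with planted midpoints, and first-order
inactivation time courses.  All generators are deterministic given a seed.

The generated alignment places the reference so that its ungapped numbering
*is* the unified numbering (unified position p at ungapped index p−1), which
makes the anchor table trivial by construction; insertion columns (reference
gapped) and per-sequence deletions exercise the mapping logic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .alignment import AMINO_ACIDS, GAP, AlignedSequenceSet
from .errors import AtakitError, ConfigurationError
from .fingerprint import DEFAULT_SCHEMA, FingerprintSchema, load_library
from .kinetics import AssayConstants, KineticTrace
from .stability import ConditionLabel, StabilityTimeCourse
from .thermal import MeltingCurve, MeltParams

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")


def _default_fingerprints() -> dict[str, str]:
    return load_library().fingerprints()


@dataclass
class SimConfig:
    """One bundle of generator settings (YAML round-trippable).

    Defaults emulate the characterized study system: a 15-member subfamily
    alignment (five reference enzymes + ten investigated sequences) with the
    curated fingerprints planted, 10-minute assay traces sampled every 30 s,
    a 20–95 °C melting scan, and an 8-point stability schedule over 24 h.
    """

    seed: int = 0
    n_sequences: int = 15
    alignment_length: int = 400
    reference_id: str = "TA-3N5M"
    planted_fingerprints: dict[str, str] = field(default_factory=_default_fingerprints)
    #: identity to the reference: one fraction for all sequences, or a
    #: per-sequence-id mapping; None leaves identity uncontrolled (~40%)
    target_identity: float | dict[str, float] | None = None
    trace_noise_sd: float = 0.002  # absorbance units
    melt_params: MeltParams = field(default_factory=lambda: MeltParams(midpoint_C=70.0))
    melt_noise_sd: float = 0.001  # ratio units
    inactivation_rate_per_h: float = 0.05
    sampling_schedule_h: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0)
    residual_noise_sd: float = 2.0  # percentage points

    def __post_init__(self) -> None:
        for sid, fp in self.planted_fingerprints.items():
            if len(fp) != len(DEFAULT_SCHEMA):
                raise ConfigurationError(
                    f"planted fingerprint for {sid!r} must have {len(DEFAULT_SCHEMA)} residues"
                )
            bad = set(fp.upper()) - set(AMINO_ACIDS)
            if bad:
                raise ConfigurationError(f"fingerprint for {sid!r} has non-amino-acid letters {bad}")
        if self.trace_noise_sd < 0 or self.melt_noise_sd < 0 or self.residual_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.inactivation_rate_per_h < 0:
            raise ConfigurationError("inactivation rate must be >= 0")
        if self.target_identity is not None:
            vals = (
                self.target_identity.values()
                if isinstance(self.target_identity, dict)
                else [self.target_identity]
            )
            if not all(0.0 <= v <= 1.0 for v in vals):
                raise ConfigurationError("target_identity must lie in [0, 1]")


def save_config(cfg: SimConfig, path: str | Path) -> None:
    """Write a config as nested key–value YAML."""
    data = asdict(cfg)
    data["melt_params"] = asdict(cfg.melt_params)
    data["sampling_schedule_h"] = list(cfg.sampling_schedule_h)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "melt_params" in data:
        data["melt_params"] = MeltParams(**data["melt_params"])
    if "sampling_schedule_h" in data:
        data["sampling_schedule_h"] = tuple(data["sampling_schedule_h"])
    return SimConfig(**data)


def gen_alignment(cfg: SimConfig, schema: FingerprintSchema = DEFAULT_SCHEMA) -> AlignedSequenceSet:
    """Generate a gapped alignment with planted fingerprints.

    The reference sequence is ungapped apart from insertion columns shared by
    the whole alignment; each planted fingerprint appears verbatim at the
    mapped columns of its sequence.  When ``target_identity`` is set, the
    identity of every non-reference sequence *to the reference* (identical
    pairs over columns where both are ungapped) is hit exactly up to the
    rounding of the mismatch count; gaps are placed only outside fingerprint
    columns so planting is never destroyed.
    """
    rng = np.random.default_rng(cfg.seed)
    ref_len = max(schema.positions)  # reference ungapped numbering = unified numbering
    if cfg.alignment_length < ref_len:
        raise ConfigurationError(
            f"alignment_length {cfg.alignment_length} < {ref_len} ungapped reference positions needed"
        )
    if cfg.reference_id not in cfg.planted_fingerprints:
        raise ConfigurationError(f"reference {cfg.reference_id!r} has no planted fingerprint")

    ids = [cfg.reference_id] + [i for i in cfg.planted_fingerprints if i != cfg.reference_id]
    for k in range(len(ids), cfg.n_sequences):
        ids.append(f"seq-{k + 1}")
    ids = ids[: max(cfg.n_sequences, len(cfg.planted_fingerprints))]

    fp_idx = np.array([p - 1 for p in schema.positions])  # 0-based ungapped ref indices
    background = np.setdiff1d(np.arange(ref_len), fp_idx)

    ref = rng.choice(_AA, size=ref_len).astype("U1")
    ref[fp_idx] = list(cfg.planted_fingerprints[cfg.reference_id].upper())

    n_ins = cfg.alignment_length - ref_len
    # slots between/around reference residues where shared insertion columns go
    ins_slots = np.sort(rng.integers(0, ref_len + 1, size=n_ins))

    rows: dict[str, np.ndarray] = {cfg.reference_id: ref.copy()}
    for sid in ids:
        if sid == cfg.reference_id:
            continue
        seq = ref.copy()
        planted = cfg.planted_fingerprints.get(sid)
        if planted is not None:
            seq[fp_idx] = list(planted.upper())
        # deletions only at background columns, so fingerprints stay intact
        n_del = int(rng.integers(2, 7))
        del_idx = rng.choice(background, size=n_del, replace=False)
        keep_bg = np.setdiff1d(background, del_idx)
        target = (
            cfg.target_identity.get(sid)
            if isinstance(cfg.target_identity, dict)
            else cfg.target_identity
        )
        if target is None:
            sub_mask = rng.random(len(keep_bg)) < 0.6
            sub_idx = keep_bg[sub_mask]
        else:
            comparable = ref_len - n_del
            fp_mismatch = int(np.sum(seq[fp_idx] != ref[fp_idx]))
            want = int(round((1.0 - target) * comparable))
            n_sub = max(want - fp_mismatch, 0)
            n_sub = min(n_sub, len(keep_bg))
            sub_idx = rng.choice(keep_bg, size=n_sub, replace=False)
        for i in sub_idx:
            choices = _AA[_AA != ref[i].encode()]
            seq[i] = rng.choice(choices).decode()
        seq[del_idx] = GAP
        rows[sid] = seq

    records = []
    for sid in ids:
        if sid not in rows:  # filler sequences beyond the planted set
            seq = ref.copy()
            sub_mask = rng.random(ref_len) < 0.6
            for i in np.where(sub_mask)[0]:
                choices = _AA[_AA != ref[i].encode()]
                seq[i] = rng.choice(choices).decode()
            rows[sid] = seq
        # splice shared insertion columns into the ungapped row
        seq = rows[sid]
        out = []
        prev = 0
        ins_fill = rng.random(n_ins)  # per-sequence: residue or gap in insertion columns
        for k, slot in enumerate(ins_slots):
            out.append("".join(seq[prev:slot]))
            if sid == cfg.reference_id:
                out.append(GAP)
            else:
                out.append(rng.choice(_AA).decode() if ins_fill[k] < 0.5 else GAP)
            prev = slot
        out.append("".join(seq[prev:]))
        records.append((sid, "".join(out)))
    return AlignedSequenceSet(tuple(records))


def gen_trace(
    activity_U_per_mL: float,
    constants: AssayConstants,
    duration_min: float = 10.0,
    interval_s: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 0.05,
    label: str = "reaction",
) -> KineticTrace:
    """Linear absorbance trace whose slope encodes a planted activity.

    The noiseless slope is ``activity · factor / 60`` ΔAbs/min — the exact
    inverse of ``activity = slope · 60 / factor`` — sampled on the grid
    t = 0 … duration at the given interval (defaults: 10 min every 30 s,
    i.e. 21 points).
    """
    if activity_U_per_mL < 0:
        raise AtakitError("activity must be non-negative")
    if duration_min <= 0 or interval_s <= 0:
        raise ConfigurationError("duration and interval must be positive")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    slope = activity_U_per_mL * constants.factor / 60.0
    n = int(round(duration_min * 60.0 / interval_s)) + 1
    t = np.arange(n) * interval_s / 60.0
    a = intercept + slope * t
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    wavelength = 245.0 if constants.name == "acetophenone" else 470.0
    return KineticTrace(t, a, wavelength_nm=wavelength, label=label)


def gen_melting_curve(
    melt_params: MeltParams,
    grid_C: tuple[float, float, float] = (20.0, 95.0, 0.25),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltingCurve:
    """Two-state van't Hoff melting curve on a temperature grid.

    ``grid_C`` is (start, stop, step) in °C, stop inclusive.  The planted
    midpoint must lie inside the grid.
    """
    lo, hi, step = grid_C
    if not lo < melt_params.midpoint_C < hi:
        raise ConfigurationError(
            f"midpoint {melt_params.midpoint_C} °C outside the {lo}-{hi} °C grid"
        )
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    n = int(round((hi - lo) / step)) + 1
    t = lo + np.arange(n) * step
    r = melt_params.signal(t)
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return MeltingCurve(t, r)


def gen_inactivation(
    rate_per_h: float,
    schedule_h: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: ConditionLabel | None = None,
    initial_activity_U_per_mL: float = 1.0,
) -> StabilityTimeCourse:
    """First-order inactivation course: residual(t) = 100·exp(−k·t).

    The first schedule point is the reference sample, so residual there is
    exactly 100 (noise applies to later samples only); noisy residuals are
    floored at a small positive value to keep log-linear fitting defined.
    """
    if rate_per_h < 0:
        raise AtakitError("inactivation rate must be non-negative")
    t = np.asarray(schedule_h, dtype=float)
    if len(t) < 2 or not np.all(np.diff(t) > 0):
        raise ConfigurationError("schedule must be >=2 strictly increasing times")
    residual = 100.0 * np.exp(-rate_per_h * (t - t[0]))
    if noise_sd > 0:
        eps = np.random.default_rng(seed).normal(0.0, noise_sd, size=len(t))
        eps[0] = 0.0  # reference sample defines 100%
        residual = np.maximum(residual + eps, 1e-6)
    cond = condition or ConditionLabel(mode="resting")
    activity = residual / 100.0 * initial_activity_U_per_mL
    return StabilityTimeCourse(cond, t, activity, residual_pct=residual)
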