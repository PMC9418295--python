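"""CSV/TSV readers and writers for traces, melting curves and stability data.

Formats (all plain text, header included):

* kinetic trace:    ``time_min,absorbance``
* melting curve:    ``temp_C,ratio``
* stability course: ``time_h,residual_pct``

Long-format trace files may carry extra ``well``/``label`` columns; a label
column is honoured when present.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .kinetics import KineticTrace
from .stability import ConditionLabel, StabilityTimeCourse
from .thermal import MeltingCurve


def _fmt(v: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    return repr(float(v))


def _require(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} (found {list(df.columns)})")


def read_trace(path: str | Path, label: str = "reaction") -> KineticTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ("time_min", "absorbance"), path)
    if "label" in df.columns:
        sub = df[df["label"] == label]
        if sub.empty:
            raise FormatError(f"{path}: no rows with label {label!r}")
        df = sub
    return KineticTrace(df["time_min"].to_numpy(float), df["absorbance"].to_numpy(float), label=label)


def write_trace(trace: KineticTrace, path: str | Path) -> None:
    pd.DataFrame({"time_min": trace.time_min, "absorbance": trace.absorbance}).to_csv(
        path, index=False, float_format=_fmt
    )


def read_melting_curve(path: str | Path) -> MeltingCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ("temp_C", "ratio"), path)
    return MeltingCurve(df["temp_C"].to_numpy(float), df["ratio"].to_numpy(float))


def write_melting_curve(curve: MeltingCurve, path: str | Path) -> None:
    pd.DataFrame({"temp_C": curve.temp_C, "ratio": curve.ratio}).to_csv(path, index=False, float_format=_fmt)


def read_stability(path: str | Path, condition: ConditionLabel | None = None) -> StabilityTimeCourse:
    """Read a residual-activity course.

    Condition metadata may come from long-format columns
    (``mode,temp_C,plp_mM,cosolvent,pct_v_v``) or be supplied explicitly;
    an explicit ``condition`` wins.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ("time_h", "residual_pct"), path)
    if condition is None:
        if "mode" in df.columns:
            cs = None
            if "cosolvent" in df.columns and pd.notna(df["cosolvent"].iloc[0]):
                cs = (str(df["cosolvent"].iloc[0]), float(df.get("pct_v_v", pd.Series([0.0])).iloc[0]))
            condition = ConditionLabel(
                mode=str(df["mode"].iloc[0]),
                temperature_C=float(df["temp_C"].iloc[0]) if "temp_C" in df.columns else 40.0,
                plp_mM=float(df["plp_mM"].iloc[0]) if "plp_mM" in df.columns else 0.1,
                co_solvent=cs,
            )
        else:
            condition = ConditionLabel(mode="resting")
    residual = df["residual_pct"].to_numpy(float)
    return StabilityTimeCourse(
        condition, df["time_h"].to_numpy(float), residual / 100.0, residual_pct=residual
    )


def write_stability(course: StabilityTimeCourse, path: str | Path) -> None:
    pd.DataFrame({"time_h": course.time_h, "residual_pct": course.residual_pct}).to_csv(
        path, index=False, float_format=_fmt
    )
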