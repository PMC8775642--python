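"""CSV reading and writing for trials and recovery series.

Two tidy schemas:

``trials.csv``
    participant_id, push_force_N, tool, tool_weight_kg, mvc_N, met_min,
    ms0_N, cr10_0 — one row per exhaustive push.

``recovery.csv``
    participant_id, push_force_N, tool, t_min, ms_N, cr10 — long format,
    one row per trial per minute (the 0-min row is stored and must agree
    with the trial's MS0).

Numeric round trips are lossless: floats are written with their shortest
exact decimal representation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import Condition, FatigueTrial, RecoverySeries
from .errors import RecordError, SchemaError

TRIALS_COLUMNS = [
    "participant_id",
    "push_force_N",
    "tool",
    "tool_weight_kg",
    "mvc_N",
    "met_min",
    "ms0_N",
    "cr10_0",
]

RECOVERY_COLUMNS = ["participant_id", "push_force_N", "tool", "t_min", "ms_N", "cr10"]

_TRIAL_NUMERIC = ["push_force_N", "tool_weight_kg", "mvc_N", "met_min", "ms0_N", "cr10_0"]
_RECOVERY_NUMERIC = ["push_force_N", "t_min", "ms_N", "cr10"]


def _float_repr(value) -> str:
    return repr(float(value))


def _check_columns(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, columns: list[str], path: str | Path) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"in column {col!r} at row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise SchemaError(f"{path}: missing value in column {col!r} at row {row}")
        df[col] = coerced
    return df


def read_trials(path: str | Path) -> list[FatigueTrial]:
    """Read and validate a trials CSV; row indices appear in error messages."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TRIALS_COLUMNS, path)
    df = _coerce_numeric(df, _TRIAL_NUMERIC, path)
    trials = []
    for row_idx, row in df.iterrows():
        try:
            condition = Condition(
                push_force=float(row["push_force_N"]),
                tool_label=str(row["tool"]),
                tool_weight=float(row["tool_weight_kg"]),
            )
            trial = FatigueTrial(
                participant_id=str(row["participant_id"]),
                condition=condition,
                mvc=float(row["mvc_N"]),
                met=float(row["met_min"]),
                ms0=float(row["ms0_N"]),
                cr10_0=float(row["cr10_0"]),
            )
        except RecordError as err:
            raise RecordError(str(err), row=int(row_idx)) from err
        trials.append(trial)
    return trials


def write_trials(trials: list[FatigueTrial], path: str | Path) -> None:
    """Write trials to CSV (header always written, even for an empty list)."""
    rows = [
        {
            "participant_id": t.participant_id,
            "push_force_N": t.condition.push_force,
            "tool": t.condition.tool_label,
            "tool_weight_kg": t.condition.tool_weight,
            "mvc_N": t.mvc,
            "met_min": t.met,
            "ms0_N": t.ms0,
            "cr10_0": t.cr10_0,
        }
        for t in trials
    ]
    # shortest exact decimal representation, so reads are lossless
    pd.DataFrame(rows, columns=TRIALS_COLUMNS).to_csv(
        path, index=False, float_format=_float_repr
    )


def read_recovery(path: str | Path, trials: list[FatigueTrial]) -> list[RecoverySeries]:
    """Read the long-format recovery CSV and attach each series to its trial.

    Each (participant, force, tool) group becomes one :class:`RecoverySeries`;
    a group without a matching trial, or whose 0-min strength disagrees with
    the trial's MS0, is a record error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, RECOVERY_COLUMNS, path)
    df = _coerce_numeric(df, _RECOVERY_NUMERIC, path)
    by_key = {t.key: t for t in trials}
    series = []
    for key, group in df.groupby(["participant_id", "push_force_N", "tool"], sort=False):
        trial_key = (str(key[0]), float(key[1]), str(key[2]))
        trial = by_key.get(trial_key)
        if trial is None:
            raise RecordError(f"recovery series {trial_key} has no matching trial")
        group = group.sort_values("t_min")
        series.append(
            RecoverySeries(
                trial=trial,
                times=group["t_min"].to_numpy(),
                ms=group["ms_N"].to_numpy(),
                cr10=group["cr10"].to_numpy(),
            )
        )
    return series


def write_recovery(series: list[RecoverySeries], path: str | Path) -> None:
    """Write recovery series as a long CSV, one row per trial per time point."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.trial.participant_id,
                    "push_force_N": s.trial.condition.push_force,
                    "tool": s.trial.condition.tool_label,
                    "t_min": s.times,
                    "ms_N": s.ms,
                    "cr10": s.cr10,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)[RECOVERY_COLUMNS]
    else:
        out = pd.DataFrame(columns=RECOVERY_COLUMNS)
    out.to_csv(path, index=False, float_format=_float_repr)
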