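"""Reading and writing the long-format trial table (the on-disk data contract).

One row per continuous-report test trial, delimited text (CSV, UTF-8, header
row), columns exactly the trial-record fields, angles in decimal degrees with
full round-trip precision, missing responses encoded as empty fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import GROUPS, PHASES, TRIAL_COLUMNS

__all__ = ["TrialTableError", "read_trial_table", "write_trial_table", "TRIAL_COLUMNS"]

_ANGLE_COLUMNS = ("target", "response", "schema_mean_current", "schema_mean_original")


class TrialTableError(ValueError):
    """Malformed trial table; the message carries file line numbers."""


def write_trial_table(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the canonical column order.

    Floats are written with shortest round-trip repr, so a write/read cycle
    reproduces every angle exactly; missing responses become empty fields.
    Output is byte-deterministic for identical input frames.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialTableError(f"trial table is missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def _fail(problems):
    raise TrialTableError("; ".join(problems))


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_trial_table`.

    Validation errors (missing columns, unparseable or out-of-range angles,
    unknown labels) are reported with 1-based file line numbers (header is
    line 1).  Tolerates CRLF line endings.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "category": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing required column(s): {missing}")
    problems = []

    def lines(bad_index) -> str:
        nums = [int(i) + 2 for i in bad_index[:5]]
        return f"line(s) {nums}"

    for col in _ANGLE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_missing = df[col].isna()
        unparseable = vals.isna() & ~raw_missing
        if unparseable.any():
            problems.append(f"unparseable {col} at {lines(df.index[unparseable])}")
        if col != "response" and raw_missing.any():
            problems.append(f"missing {col} at {lines(df.index[raw_missing])}")
        present = vals.notna()
        out_of_range = present & ((vals < 0.0) | (vals >= 360.0))
        if out_of_range.any():
            problems.append(
                f"{col} outside [0, 360) at {lines(df.index[out_of_range])}"
            )
        df[col] = vals
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        problems.append(f"unknown group label at {lines(df.index[bad_group])}")
    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        problems.append(f"unknown phase label at {lines(df.index[bad_phase])}")
    bad_quad = ~df["quadrant"].isin(("inside", "outside"))
    if bad_quad.any():
        problems.append(f"unknown quadrant label at {lines(df.index[bad_quad])}")
    if problems:
        _fail(problems)
    df["block"] = df["block"].astype(int)
    df["is_critical"] = df["is_critical"].astype(bool)
    return df[TRIAL_COLUMNS]
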