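"""Canonical trial-table schema, readers and writers.

The interchange format is a UTF-8 comma-separated table with a header row,
one row per commanded response.  Core columns:

====================  =====================================================
individual_id         subject label
session_id            session label, unique per subject x session
trial_index           1-based trial position within the session
condition             one of the trial-condition labels (see design module)
action_command        the behavior the subject was commanded to perform
repeat_position       0 control response, 1 first/only repeat, 2 second
response              behavior actually performed
correct               0/1
delay_s               staircase delay in seconds; empty unless the
                      condition is delayed_repeat
====================  =====================================================

Extra columns pass through validation untouched, and a column-mapping hook
lets externally deposited tables with different headers be ingested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CONDITIONS

__all__ = ["REQUIRED_COLUMNS", "SchemaError", "validate_trials", "read_trials", "write_trials"]

REQUIRED_COLUMNS = (
    "individual_id",
    "session_id",
    "trial_index",
    "condition",
    "action_command",
    "repeat_position",
    "response",
    "correct",
    "delay_s",
)


class SchemaError(ValueError):
    """A trial table violates the canonical schema."""


def _bad_rows(mask: pd.Series, what: str, errors: list[str]) -> None:
    if mask.any():
        rows = [int(i) for i in mask[mask].index[:10]]
        errors.append(f"{what} (rows {rows}{', ...' if mask.sum() > 10 else ''})")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the canonical schema.

    Returns the table (with ``correct`` coerced to int and ``delay_s`` to
    float) or raises :class:`SchemaError` listing every violation with the
    offending row numbers.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = trials.copy()
    errors: list[str] = []

    _bad_rows(~df["condition"].isin(CONDITIONS), "unknown condition label", errors)
    correct_ok = df["correct"].isin([0, 1, True, False])
    _bad_rows(~correct_ok, "correct must be 0/1", errors)
    _bad_rows(~df["repeat_position"].isin([0, 1, 2]), "repeat_position must be 0, 1 or 2", errors)

    delay = pd.to_numeric(df["delay_s"], errors="coerce")
    is_delayed = df["condition"] == "delayed_repeat"
    _bad_rows(is_delayed & ~(delay > 0), "delayed_repeat rows need delay_s > 0", errors)
    _bad_rows(~is_delayed & delay.notna(), "delay_s must be empty off the delayed condition", errors)

    dup = df.duplicated(
        subset=["individual_id", "session_id", "trial_index", "repeat_position"],
        keep=False,
    )
    _bad_rows(dup, "duplicate (session, trial_index, repeat_position)", errors)

    if errors:
        raise SchemaError("; ".join(errors))
    df["correct"] = df["correct"].astype(int)
    df["delay_s"] = delay
    return df


def read_trials(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a trial CSV.

    ``column_map`` maps external column names to canonical ones (for
    ingesting deposited tables whose headers differ); unmapped extra
    columns are preserved.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_trials(df)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Validate and write a trial table as the canonical CSV."""
    validate_trials(trials).to_csv(path, index=False)
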