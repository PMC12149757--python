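"""CSV schemas and validated tabular I/O for trials and self-reports.

Trials and self-reports are flat UTF-8 CSVs with a header row.  Category
labels for stimuli/responses are free strings (e.g. signal/noise or
real/fake) but must be used consistently; structural fields (session, phase,
advice_correct, timepoint, rating, item) are validated against their allowed
values, with row numbers reported on failure.  Unknown extra columns are
preserved on a round trip.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import REPORT_COLUMNS, SELFREPORT_ITEMS, TRIAL_COLUMNS

PHASES = {"pre-error", "error", "post-error", "none"}
ADVICE_CORRECT = {"true", "false", "n/a"}


class SchemaError(ValueError):
    """A table violates the documented column schema."""


def _rows(mask: pd.Series) -> str:
    # +2: one for the header line, one for 0- vs 1-based indexing
    rows = (mask[mask].index + 2).tolist()
    shown = ", ".join(map(str, rows[:10]))
    return shown + (" ..." if len(rows) > 10 else "")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trials table lacks columns {missing}")
    t = trials.reset_index(drop=True)
    checks = {
        "session not in {1, 2}": ~t["session"].isin([1, 2]),
        f"phase not in {sorted(PHASES)}": ~t["phase"].isin(PHASES),
        f"advice_correct not in {sorted(ADVICE_CORRECT)}":
            ~t["advice_correct"].astype(str).isin(ADVICE_CORRECT),
        "Session-1 trial carries advice":
            (t["session"] == 1) & (t["advice_shown"] != "none"),
    }
    cats = set(t["true_category"].unique())
    if len(cats) > 2:
        raise SchemaError(f"more than two stimulus categories: {sorted(cats)}")
    checks["response outside the stimulus categories"] = ~t["response"].isin(cats)
    advised = t["advice_shown"] != "none"
    checks["advice outside the stimulus categories"] = (
        advised & ~t["advice_shown"].isin(cats))
    checks["advice_correct inconsistent with advice and truth"] = advised & (
        (t["advice_shown"] == t["true_category"])
        != (t["advice_correct"].astype(str) == "true"))
    for what, mask in checks.items():
        if mask.any():
            raise SchemaError(f"{what} (rows {_rows(mask)})")
    return t


def validate_reports(reports: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REPORT_COLUMNS if c not in reports.columns]
    if missing:
        raise SchemaError(f"self-report table lacks columns {missing}")
    r = reports.reset_index(drop=True)
    checks = {
        "timepoint not in 1..5": ~r["timepoint"].isin(range(1, 6)),
        f"item not in {sorted(SELFREPORT_ITEMS)}": ~r["item"].isin(SELFREPORT_ITEMS),
        "rating not an integer in 1..7": ~r["rating"].isin(range(1, 8)),
    }
    for what, mask in checks.items():
        if mask.any():
            raise SchemaError(f"{what} (rows {_rows(mask)})")
    dup = r.duplicated(["participant_id", "timepoint", "item"])
    if dup.any():
        raise SchemaError(f"duplicate participant x timepoint x item (rows {_rows(dup)})")
    return r


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    validate_trials(trials).to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    # keep_default_na: "n/a" is a legitimate advice_correct level, not missing
    t = pd.read_csv(path, dtype={"advice_correct": str}, keep_default_na=False,
                    na_values=[""])
    if "response_correct" in t.columns and t["response_correct"].dtype == object:
        t["response_correct"] = t["response_correct"].astype(str).str.lower() == "true"
    return validate_trials(t)


def write_reports(reports: pd.DataFrame, path: str | Path) -> None:
    validate_reports(reports).to_csv(path, index=False)


def read_reports(path: str | Path) -> pd.DataFrame:
    return validate_reports(pd.read_csv(path))
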