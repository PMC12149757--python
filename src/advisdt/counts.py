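"""SDT bookkeeping: hit/false-alarm tabulation and the log-linear correction."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPINGS = ("all", "phase", "advice")

COUNT_COLUMNS = [
    "participant_id", "condition", "session", "stratum",
    "n_signal_trials", "n_noise_trials", "hits", "false_alarms",
]


def tabulate_counts(
    trials: pd.DataFrame,
    grouping: str = "all",
    signal_category: str = "signal",
) -> pd.DataFrame:
    """Count hits and false alarms per participant and analysis cell.

    ``grouping`` selects the stratification of trials within a session:
    ``"all"`` pools every trial, ``"phase"`` splits the advised session by
    experiment phase, ``"advice"`` splits it by advice correctness.  A hit is
    a "signal" response to a signal stimulus; a false alarm is a "signal"
    response to a noise stimulus, where the designated ``signal_category``
    defines which of the two class labels plays the signal role.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    t = trials.copy()
    if grouping == "all":
        t["stratum"] = "all"
    elif grouping == "phase":
        t["stratum"] = np.where(t["session"] == 1, "all", t["phase"].astype(str))
    else:
        t["stratum"] = np.where(
            t["session"] == 1,
            "all",
            np.where(t["advice_correct"].astype(str) == "true", "correct", "incorrect"),
        )

    is_signal = t["true_category"] == signal_category
    said_signal = t["response"] == signal_category
    t["_sig"] = is_signal.astype(int)
    t["_noi"] = 1 - t["_sig"]
    t["_hit"] = (is_signal & said_signal).astype(int)
    t["_fa"] = (~is_signal & said_signal).astype(int)

    keys = ["participant_id", "condition", "session", "stratum"]
    out = (
        t.groupby(keys, sort=True, observed=True)[["_sig", "_noi", "_hit", "_fa"]]
        .sum()
        .reset_index()
        .rename(columns={
            "_sig": "n_signal_trials", "_noi": "n_noise_trials",
            "_hit": "hits", "_fa": "false_alarms",
        })
    )
    return out[COUNT_COLUMNS]


def drop_degenerate_cells(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove participant x stratum rows lacking signal or noise trials.

    Small strata (e.g. the incorrect-advice split at short designs) can miss
    one trial type entirely; such cells are excluded from the fit with a
    logged warning rather than imputed.
    """
    bad = (counts["n_signal_trials"] < 1) | (counts["n_noise_trials"] < 1)
    if bad.any():
        dropped = counts.loc[bad, ["participant_id", "stratum"]]
        logger.warning(
            "dropping %d degenerate cell(s) without both trial types: %s",
            int(bad.sum()),
            "; ".join(f"{r.participant_id}/{r.stratum}" for r in dropped.itertuples()),
        )
    return counts[~bad].reset_index(drop=True)


def loglinear_rates(
    hits: np.ndarray | float,
    n_signal_trials: np.ndarray | float,
    false_alarms: np.ndarray | float,
    n_noise_trials: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-linear corrected hit and false-alarm rates.

    Adds 0.5 to the hit and false-alarm frequencies and 1 to each trial
    total, so the returned rates are strictly inside (0, 1) and d'/c stay
    estimable even for perfect or empty cells.
    """
    hits = np.asarray(hits, dtype=float)
    n_sig = np.asarray(n_signal_trials, dtype=float)
    fas = np.asarray(false_alarms, dtype=float)
    n_noi = np.asarray(n_noise_trials, dtype=float)
    if np.any(n_sig < 1) or np.any(n_noi < 1):
        raise ValueError("degenerate cell: needs at least one signal and one noise trial")
    if np.any(hits > n_sig) or np.any(fas > n_noi) or np.any(hits < 0) or np.any(fas < 0):
        raise ValueError("counts must satisfy 0 <= hits <= n_signal, 0 <= FA <= n_noise")
    return (hits + 0.5) / (n_sig + 1.0), (fas + 0.5) / (n_noi + 1.0)
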