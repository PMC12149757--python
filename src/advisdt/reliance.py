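"""Behavioral reliance measures for advised classification.

Acceptance rate: fraction of advised trials on which the final decision
equals the advice.  Switch percentage: among advised trials where the
participant's own unadvised (Session 1) decision on the same stimulus
differed from the advice, the fraction on which the advised decision equals
the advice.  Both are reported as contingency tables with explicit counts so
margins stay auditable; cells with empty denominators are kept with an
undefined (NaN) rate rather than dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SPLIT_VARIABLES = {"advice_correct", "condition", "participant_id"}

RATE_COLUMNS = ["metric", "n_not", "n_yes", "rate"]


def _rate_table(frame: pd.DataFrame, yes: pd.Series, group_by: list[str],
                metric: str) -> pd.DataFrame:
    t = frame[group_by].copy() if group_by else pd.DataFrame(index=frame.index)
    t["_yes"] = yes.astype(int)
    t["_not"] = 1 - t["_yes"]
    if group_by:
        agg = t.groupby(group_by, sort=True, observed=True)[["_not", "_yes"]].sum().reset_index()
    else:
        agg = pd.DataFrame({"_not": [t["_not"].sum()], "_yes": [t["_yes"].sum()]})
    agg["metric"] = metric
    denom = agg["_not"] + agg["_yes"]
    agg["rate"] = np.where(denom > 0, agg["_yes"] / denom.replace(0, np.nan), np.nan)
    agg = agg.rename(columns={"_not": "n_not", "_yes": "n_yes"})
    return agg[group_by + RATE_COLUMNS]


def _advised(trials_s2: pd.DataFrame) -> pd.DataFrame:
    adv = trials_s2[(trials_s2["session"] == 2)
                    & (trials_s2["advice_shown"] != "none")].copy()
    if adv.empty:
        raise ValueError("no advised Session-2 trials in input")
    return adv


def acceptance_rate(trials_s2: pd.DataFrame,
                    group_by: list[str] | None = None) -> pd.DataFrame:
    """Acceptance-rate table over advised trials, optionally grouped."""
    group_by = list(group_by or [])
    adv = _advised(trials_s2)
    return _rate_table(adv, adv["response"] == adv["advice_shown"], group_by,
                       "acceptance")


def switch_percentage(trials_s2: pd.DataFrame, trials_s1: pd.DataFrame,
                      group_by: list[str] | None = None) -> pd.DataFrame:
    """Switch-percentage table, pairing sessions on participant x stimulus."""
    group_by = list(group_by or [])
    adv = _advised(trials_s2)
    s1 = trials_s1[trials_s1["session"] == 1]
    key = ["participant_id", "stimulus_id"]
    s1_resp = s1[key + ["response"]].rename(columns={"response": "response_s1"})
    if s1_resp.duplicated(key).any():
        dupes = s1_resp[s1_resp.duplicated(key)][key].values.tolist()
        raise ValueError(f"duplicate Session-1 keys: {dupes[:5]}")
    merged = adv.merge(s1_resp, on=key, how="left", validate="m:1")
    unpaired = merged[merged["response_s1"].isna()]
    if len(unpaired):
        keys = unpaired[key].values.tolist()
        raise ValueError(f"advised trials without a paired Session-1 trial: {keys[:5]}")
    eligible = merged[merged["response_s1"] != merged["advice_shown"]]
    table = _rate_table(eligible, eligible["response"] == eligible["advice_shown"],
                        group_by, "switch")
    if group_by:
        # keep groups whose switch denominator is empty, with an undefined rate
        all_groups = adv[group_by].drop_duplicates()
        table = all_groups.merge(table, on=group_by, how="left")
        table["metric"] = "switch"
        table[["n_not", "n_yes"]] = table[["n_not", "n_yes"]].fillna(0).astype(int)
        table = table.sort_values(group_by).reset_index(drop=True)
    return table


def contingency_table(trials_s2: pd.DataFrame, trials_s1: pd.DataFrame | None,
                      split_variables: list[str]) -> pd.DataFrame:
    """Acceptance (and, when Session 1 is given, switch) cells plus margins.

    Margins are emitted as extra rows with the label ``"total"`` in each
    split column; by construction their counts equal the sums of the cells.
    """
    unknown = set(split_variables) - SPLIT_VARIABLES
    if unknown:
        raise ValueError(f"unknown split variable(s) {sorted(unknown)}; "
                         f"allowed: {sorted(SPLIT_VARIABLES)}")
    split = list(split_variables)
    pieces = []

    def one_metric(fn):
        cells = fn(split)
        cells["margin"] = False
        pieces.append(cells)
        for drop in range(1, len(split) + 1):
            reduced = split[:-drop]
            marg = fn(reduced)
            for col in split[len(split) - drop:]:
                marg[col] = "total"
            marg["margin"] = True
            pieces.append(marg)

    one_metric(lambda g: acceptance_rate(trials_s2, g))
    if trials_s1 is not None:
        one_metric(lambda g: switch_percentage(trials_s2, trials_s1, g))
    out = pd.concat(pieces, ignore_index=True)
    return out[split + RATE_COLUMNS + ["margin"]]


def rate_percent(n_not: int, n_yes: int) -> float:
    """Rate as a percentage rounded to 2 decimals (table display convention)."""
    denom = n_not + n_yes
    if denom == 0:
        return float("nan")
    return round(100.0 * n_yes / denom, 2)


def correlate(x, y) -> float:
    """Pearson product-moment correlation of two paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
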