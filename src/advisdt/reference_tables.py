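"""Published reliance contingency counts from the original two-scenario study.

The cells give, pooled over the study's 131 participants, how often advice
was accepted (the advised decision equalled the advice) and how often
participants switched to the advice (the advised decision equalled the
advice although the participant's own unadvised decision on the same
stimulus differed from it), split by advice correctness and instruction
condition.  They serve as fixed inputs for recomputing the study's
acceptance rates and switch percentages; the switch cells follow the verbal
definition (yes = switched to the advice), which matches the per-cell table
of the original report.
"""

from __future__ import annotations

import pandas as pd

# (advice_correct, condition) -> (n_not, n_yes)
ACCEPTANCE_CELLS = {
    ("false", "distrust"): (1490, 1182),
    ("false", "information-only"): (1657, 1413),
    ("true", "distrust"): (1562, 8942),
    ("true", "information-only"): (1704, 10346),
}

SWITCH_CELLS = {
    ("false", "distrust"): (1181, 616),
    ("false", "information-only"): (1329, 709),
    ("true", "distrust"): (891, 2583),
    ("true", "information-only"): (1067, 3044),
}


def cells_frame(metric: str) -> pd.DataFrame:
    cells = {"acceptance": ACCEPTANCE_CELLS, "switch": SWITCH_CELLS}[metric]
    rows = [
        {"metric": metric, "advice_correct": k[0], "condition": k[1],
         "n_not": v[0], "n_yes": v[1]}
        for k, v in sorted(cells.items())
    ]
    return pd.DataFrame(rows)


def marginal(metric: str, by: str | None = None) -> pd.DataFrame:
    """Sum cells over the other factor (or over both for the pooled total)."""
    f = cells_frame(metric)
    if by is None:
        out = f[["n_not", "n_yes"]].sum().to_frame().T
        out.insert(0, "metric", metric)
        return out
    return (f.groupby(by, as_index=False)[["n_not", "n_yes"]].sum()
            .assign(metric=metric))
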