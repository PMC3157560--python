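"""Detour route-choice tallies and per-rat proportion tests.

In the barrier detour tasks each completed journey yields one binary
choice: a detour whose first leg is horizontal versus one whose first leg
is vertical.  The analysis reports, per condition (journey direction,
barrier placement), the count and proportion of horizontal-first choices
with an exact (Clopper-Pearson) confidence interval, and tests the per-rat
proportions against chance with a one-sample t-test (df = n_rats - 1).

Records with a missing choice (the rat timed out) count as incomplete and
are excluded from all denominators.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

HORIZONTAL = "horizontal_first"
VERTICAL = "vertical_first"


def _completed(records: pd.DataFrame) -> pd.DataFrame:
    ok = records["choice"].isin([HORIZONTAL, VERTICAL])
    return records[ok]


def tally(
    records: pd.DataFrame, by: Sequence[str] = ("direction",), alpha: float = 0.05
) -> pd.DataFrame:
    """Horizontal-first counts, completed counts, proportions and exact
    binomial CIs per group of ``by`` columns."""
    if records.empty:
        raise ValueError("no choice records")
    done = _completed(records)
    rows = []
    for key, g in done.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        k = int((g["choice"] == HORIZONTAL).sum())
        n = len(g)
        lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
        rows.append(
            dict(zip(by, key))
            | {
                "horizontal_first": k,
                "completed": n,
                "proportion": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def per_rat_proportion_test(
    records: pd.DataFrame, null_p: float = 0.5
) -> tuple[float, int, float]:
    """One-sample t-test of per-rat horizontal-first proportions against
    ``null_p``.  Returns ``(t, df, p)`` with ``df = n_rats - 1``."""
    done = _completed(records)
    props = (
        done.assign(h=(done["choice"] == HORIZONTAL))
        .groupby("rat")["h"]
        .mean()
        .to_numpy(dtype=float)
    )
    n = len(props)
    if n < 2:
        raise ValueError("need at least two rats with completed trials")
    sd = props.std(ddof=1)
    if sd == 0.0:
        if math.isclose(props[0], null_p):
            return 0.0, n - 1, 1.0
        return math.inf if props[0] > null_p else -math.inf, n - 1, 0.0
    t, p = stats.ttest_1samp(props, popmean=null_p)
    return float(t), n - 1, float(p)
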