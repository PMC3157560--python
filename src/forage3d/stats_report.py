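"""Pooled summaries and group comparisons for OD and crossing tables.

Thin, validated wrappers over scipy/statsmodels: means +/- SEM, the paired
t-test, balanced two-factor fixed-effects ANOVA with interaction, and
one-way ANOVA with Bonferroni-adjusted pairwise t-tests.  The experimental
unit defaults to the rat (per-rat means across trials); a per-trial-day
unit is available where a caller wants trial-level pooling.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


def summarize(values: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Rows of (measure, mean, sem, n) for each named sample."""
    rows = []
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        rows.append(
            {
                "measure": name,
                "mean": float(arr.mean()),
                "sem": float(stats.sem(arr)) if len(arr) > 1 else float("nan"),
                "n": len(arr),
            }
        )
    return pd.DataFrame(rows)


def paired_compare(a, b) -> tuple[float, int, float]:
    """Paired t-test; returns (t, df, p), df = n - 1.

    Identical vectors give (0, df, 1); any other zero-variance difference
    is degenerate and rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, len(d) - 1, 1.0
        raise ValueError("differences have zero variance; t is undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)


def two_factor_anova(
    df: pd.DataFrame,
    value: str = "value",
    factor_a: str = "data_type",
    factor_b: str = "dimension",
) -> pd.DataFrame:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Returns a frame indexed by effect (factor_a, factor_b, interaction)
    with F, df_num, df_den and p.  Unbalanced designs are rejected: the
    studies this mirrors are balanced, and F values under imbalance depend
    on the sum-of-squares type.
    """
    cells = df.groupby([factor_a, factor_b])[value].count()
    la, lb = df[factor_a].nunique(), df[factor_b].nunique()
    if la < 2 or lb < 2:
        raise ValueError("need at least two levels per factor")
    if len(cells) != la * lb or cells.nunique() != 1 or cells.min() < 2:
        raise ValueError("design must be balanced with >=2 observations per cell")
    d = df.rename(columns={value: "y", factor_a: "fa", factor_b: "fb"})
    model = smf.ols("y ~ C(fa) * C(fb)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = float(table.loc["Residual", "df"])
    out = []
    for row, effect in [
        ("C(fa)", factor_a),
        ("C(fb)", factor_b),
        ("C(fa):C(fb)", "interaction"),
    ]:
        out.append(
            {
                "effect": effect,
                "F": float(table.loc[row, "F"]),
                "df_num": float(table.loc[row, "df"]),
                "df_den": df_den,
                "p": float(table.loc[row, "PR(>F)"]),
            }
        )
    return pd.DataFrame(out).set_index("effect")


def oneway_anova_bonferroni(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, tuple[int, int], float, pd.DataFrame]:
    """One-way ANOVA plus all pairwise t-tests with Bonferroni-multiplied
    p-values (capped at 1).

    Returns (F, (df_between, df_within), p, pairwise frame).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs at least two observations")
    F, p = stats.f_oneway(*arrs)
    df_b = len(arrs) - 1
    df_w = sum(len(a) for a in arrs) - len(arrs)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, raw = stats.ttest_ind(arrs[i], arrs[j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "t": float(t),
                    "p_raw": float(raw),
                    "p_bonferroni": min(1.0, float(raw) * m),
                }
            )
    return float(F), (df_b, df_w), float(p), pd.DataFrame(rows)


def per_unit_means(
    df: pd.DataFrame, value: str, unit: str = "rat"
) -> pd.Series:
    """Collapse trial-level values to one mean per experimental unit."""
    return df.groupby(unit)[value].mean()
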