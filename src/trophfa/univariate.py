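"""Univariate group comparisons: one-way ANOVA with Tukey HSD post hoc.

Individual FA proportions (arcsine square-root transformed upstream) or
biomarker indices are compared across feeding treatments with a classical
one-way ANOVA; pairwise differences use the Tukey honestly-significant-
difference test on the studentized-range distribution, with the
Tukey–Kramer correction for unequal group sizes.  Compact letter displays
summarize which groups are statistically indistinguishable.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame
    letters: dict[str, str]
    group_means: pd.Series

    def __repr__(self) -> str:  # pragma: no cover - display only
        return (
            f"AnovaResult(F_{self.df_between},{self.df_within} = {self.f_stat:.3g}, "
            f"p = {self.p_value:.4g})"
        )


def _letter_display(levels: list[str], means: pd.Series, nonsig: set[frozenset]) -> dict[str, str]:
    """Compact letters via the interval sweep over means sorted descending.

    Groups share a letter iff they belong to a maximal run of consecutively
    ranked groups that are pairwise non-significant.
    """
    order = list(means.sort_values(ascending=False).index)
    intervals: list[tuple[int, int]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and all(
            frozenset((order[p], order[q])) in nonsig
            for p in range(i, j + 2)
            for q in range(p + 1, j + 2)
        ):
            j += 1
        intervals.append((i, j))
    # drop intervals contained in earlier ones
    maximal = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv for o in intervals):
            maximal.append(iv)
    seen = []
    for iv in maximal:
        if iv not in seen:
            seen.append(iv)
    letters = {g: "" for g in order}
    alphabet = string.ascii_lowercase
    for letter_idx, (lo, hi) in enumerate(seen):
        for g in order[lo: hi + 1]:
            letters[g] += alphabet[letter_idx % len(alphabet)]
    return letters


def anova_tukey(values, groups, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Parameters
    ----------
    values : array-like of float
        Per-sample response (e.g. a transformed FA proportion).
    groups : array-like
        Treatment label per sample.
    alpha : float
        Family-wise error rate for the Tukey intervals and letters.

    Returns
    -------
    AnovaResult
        F statistic with its degrees of freedom, p-value, the Tukey table
        (group_1, group_2, mean_diff, p_adj, lower, upper, reject), and a
        compact letter display.  When every group has zero within-group
        variance the F statistic is undefined and reported as NaN with a
        warning.
    """
    y = np.asarray(values, dtype=float)
    g = pd.Series(list(groups))
    if len(y) != len(g):
        raise ValueError("values and groups differ in length")
    levels = list(dict.fromkeys(g.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if len(y) <= len(levels):
        raise ValueError("need residual degrees of freedom (n > number of groups)")
    samples = [y[(g == lev).values] for lev in levels]
    df_b = len(levels) - 1
    df_w = len(y) - len(levels)
    ss_w = sum(((s - s.mean()) ** 2).sum() for s in samples)
    grand = y.mean()
    ss_b = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    if ss_w <= 0:
        if ss_b <= 0:
            warnings.warn("zero variance everywhere; F undefined", stacklevel=2)
            f = math.nan
            p = math.nan
        else:
            warnings.warn("zero within-group variance; F infinite", stacklevel=2)
            f = math.inf
            p = 0.0
    else:
        f = (ss_b / df_b) / (ss_w / df_w)
        p = float(stats.f.sf(f, df_b, df_w))

    means = pd.Series({lev: s.mean() for lev, s in zip(levels, samples)})
    if ss_w > 0:
        res = pairwise_tukeyhsd(y, g.values, alpha=alpha)
        tuk = pd.DataFrame(
            res.summary().data[1:],
            columns=["group_1", "group_2", "mean_diff", "p_adj", "lower", "upper", "reject"],
        )
        tuk["p_adj"] = res.pvalues  # full precision, not the rounded summary
        tuk["reject"] = tuk["reject"].astype(bool)
        nonsig = {
            frozenset((r.group_1, r.group_2))
            for r in tuk.itertuples()
            if not r.reject
        }
    else:
        pairs = [
            (a, b) for i, a in enumerate(levels) for b in levels[i + 1:]
        ]
        tuk = pd.DataFrame(
            {
                "group_1": [a for a, _ in pairs],
                "group_2": [b for _, b in pairs],
                "mean_diff": [means[b] - means[a] for a, b in pairs],
                "p_adj": [1.0 if means[a] == means[b] else 0.0 for a, b in pairs],
                "lower": np.nan,
                "upper": np.nan,
            }
        )
        tuk["reject"] = tuk["p_adj"] < alpha
        nonsig = {
            frozenset((r.group_1, r.group_2)) for r in tuk.itertuples() if not r.reject
        }
    letters = _letter_display(levels, means, nonsig)
    return AnovaResult(
        f_stat=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        tukey=tuk,
        letters=letters,
        group_means=means,
    )
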