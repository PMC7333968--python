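"""Trophic-modification coefficients: trimmed-mean consumer/food ratios.

For each FA in a feeding treatment, every replicate consumer proportion is
divided by every replicate food proportion (the full cross product — five
crabs and five food samples give 25 ratios), and the coefficient is the 10%
trimmed mean of that ratio set.  Coefficients above 1 indicate FA present in
higher proportion in consumer tissue than in the food (selective retention
or biosynthesis); below 1, dilution or catabolism.  This is the calibration
coefficient of quantitative fatty-acid signature analysis (QFASA).

Ratios whose food proportion is zero are excluded from the trim set and
reported in ``n_dropped`` rather than propagated as infinities: trace FA
absent from one matrix would otherwise destroy the coefficient.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trophfa.profiles import FAProfileTable

DEFAULT_TRIM = 0.10


def pairwise_ratios(
    consumers: Sequence[float] | np.ndarray,
    foods: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """All consumer/food ratio pairs for one FA (full cross product).

    Returns an array of length ``len(consumers) * len(foods)``; pairs with a
    zero food proportion yield ``inf`` (or ``nan`` for 0/0) and are handled
    downstream.
    """
    c = np.asarray(consumers, dtype=float)
    f = np.asarray(foods, dtype=float)
    if c.size == 0 or f.size == 0:
        raise ValueError("need at least one consumer and one food replicate")
    with np.errstate(divide="ignore", invalid="ignore"):
        return (c[:, None] / f[None, :]).ravel()


def trimmed_mean(values: Sequence[float] | np.ndarray, trim_fraction: float = DEFAULT_TRIM) -> float:
    """Symmetric trimmed mean: drop ``floor(trim * n)`` values from each tail.

    Non-finite entries are excluded before trimming.  Returns NaN (with a
    warning) when no finite values remain.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    v = np.asarray(values, dtype=float)
    v = np.sort(v[np.isfinite(v)])
    n = v.size
    if n == 0:
        warnings.warn("no finite ratios; coefficient undefined", stacklevel=2)
        return math.nan
    k = math.floor(trim_fraction * n)
    return float(v[k: n - k].mean())


def modification_table(
    consumer_table: FAProfileTable,
    food_table: FAProfileTable,
    pairing: Mapping[str, str],
    trim_fraction: float = DEFAULT_TRIM,
    rank_scope: str = "treatment",
) -> pd.DataFrame:
    """Per-(treatment, FA) trophic-modification coefficients.

    Parameters
    ----------
    consumer_table, food_table :
        Profile tables sharing an FA label set; treatments are taken from
        the ``treatment`` metadata column.
    pairing :
        Maps each consumer treatment to the food treatment it was fed.
    trim_fraction :
        Fraction trimmed from each tail of the ratio set (default 0.10).
    rank_scope :
        ``"treatment"`` ranks FA by descending coefficient within each
        treatment; ``"pooled"`` ranks the full (treatment, FA) set jointly,
        matching a display of all treatments on one axis.

    Returns
    -------
    pandas.DataFrame
        Columns: treatment, fa, coefficient, log10_coefficient, se,
        n_ratios, n_dropped, rank, enriched.  ``se`` is the standard error
        of the finite ratio set; ``enriched`` flags coefficient > 1.
    """
    if rank_scope not in ("treatment", "pooled"):
        raise ValueError("rank_scope must be 'treatment' or 'pooled'")
    shared = [lab for lab in consumer_table.fa_labels if lab in set(food_table.fa_labels)]
    if not shared:
        raise ValueError("consumer and food tables share no FA labels")
    rows = []
    for cons_treat, food_treat in pairing.items():
        cons = consumer_table.by_treatment(cons_treat)
        food = food_table.by_treatment(food_treat)
        if cons.n_samples == 0:
            raise ValueError(f"consumer treatment {cons_treat!r} absent from consumer table")
        if food.n_samples == 0:
            raise ValueError(f"food treatment {food_treat!r} absent from food table")
        for lab in shared:
            ratios = pairwise_ratios(cons.values[lab].values, food.values[lab].values)
            finite = ratios[np.isfinite(ratios)]
            n_dropped = ratios.size - finite.size
            if finite.size:
                coef = trimmed_mean(finite, trim_fraction)
                se = float(finite.std(ddof=1) / np.sqrt(finite.size)) if finite.size > 1 else 0.0
            else:
                warnings.warn(
                    f"no finite ratios for {lab} in treatment {cons_treat!r}",
                    stacklevel=2,
                )
                coef, se = math.nan, math.nan
            rows.append(
                {
                    "treatment": cons_treat,
                    "fa": lab,
                    "coefficient": coef,
                    "log10_coefficient": math.log10(coef) if coef and coef > 0 else math.nan,
                    "se": se,
                    "n_ratios": int(ratios.size),
                    "n_dropped": int(n_dropped),
                }
            )
    out = pd.DataFrame(rows)
    if rank_scope == "treatment":
        out["rank"] = (
            out.groupby("treatment")["coefficient"]
            .rank(ascending=False, method="first", na_option="bottom")
            .astype(int)
        )
    else:
        out["rank"] = (
            out["coefficient"]
            .rank(ascending=False, method="first", na_option="bottom")
            .astype(int)
        )
    out["enriched"] = out["coefficient"] > 1.0
    return out
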