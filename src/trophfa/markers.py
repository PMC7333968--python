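"""Compositional transform and trophic-biomarker summaries.

The arcsine square-root transform ``asin(sqrt(p))`` (on fractions) is the
conventional variance-stabilizer for proportion data and is applied before
distance-based and univariate analyses.  Biomarker summaries condense a
profile into the class sums (SFA/MUFA/PUFA/OBCFA), the Σω3/Σω6 ratio, the
copepod marker (proportion of 20:1w11) and the bacterial marker (sum of
odd/branched-chain FA, which by convention includes 18:1w7).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from trophfa.nomenclature import (
    DEFAULT_CLASS_OVERRIDES,
    FAClass,
    classify,
    parse_fa_label,
)
from trophfa.profiles import FAProfileTable

COPEPOD_MARKER = "20:1w11"


def arcsine_sqrt_transform(table: FAProfileTable | pd.DataFrame) -> pd.DataFrame:
    """Elementwise ``asin(sqrt(p/100))`` of percent proportions, in radians.

    Maps [0, 100] percent onto [0, π/2].  Values outside [0, 100] raise.
    """
    values = table.values if isinstance(table, FAProfileTable) else table
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any() or (arr > 100).any():
        raise ValueError("proportions must lie in [0, 100] percent")
    out = np.arcsin(np.sqrt(arr / 100.0))
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return pd.DataFrame(out)


def class_sums(
    table: FAProfileTable,
    overrides: Mapping[str, FAClass] = DEFAULT_CLASS_OVERRIDES,
) -> pd.DataFrame:
    """Per-sample summed proportions by FA class.

    Returns a DataFrame with columns ``sfa_pct``, ``mufa_pct``, ``pufa_pct``,
    ``obcfa_pct``; because classification is a partition, the four columns
    sum to 100 for every sample.
    """
    cls = {lab: classify(lab, overrides) for lab in table.fa_labels}
    out = pd.DataFrame(index=table.values.index)
    for c, col in [(FAClass.SFA, "sfa_pct"), (FAClass.MUFA, "mufa_pct"),
                   (FAClass.PUFA, "pufa_pct"), (FAClass.OBCFA, "obcfa_pct")]:
        members = [lab for lab, k in cls.items() if k is c]
        out[col] = table.values[members].sum(axis=1) if members else 0.0
    return out


def omega_ratio(table: FAProfileTable) -> pd.Series:
    """Per-sample Σω3/Σω6 ratio of summed proportions.

    FA with an unknown omega position are ignored (with a warning); samples
    with Σω6 = 0 get NaN rather than infinity, also with a warning.
    """
    omega3, omega6 = [], []
    unknown = []
    for lab in table.fa_labels:
        fa = parse_fa_label(lab)
        if fa.omega_unknown:
            unknown.append(lab)
        elif fa.omega == 3:
            omega3.append(lab)
        elif fa.omega == 6:
            omega6.append(lab)
    if unknown:
        warnings.warn(
            f"FA with unknown omega position excluded from the omega-3/omega-6 "
            f"ratio: {unknown}",
            stacklevel=2,
        )
    s3 = table.values[omega3].sum(axis=1) if omega3 else pd.Series(0.0, index=table.values.index)
    s6 = table.values[omega6].sum(axis=1) if omega6 else pd.Series(0.0, index=table.values.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s3 / s6
    zero6 = s6 == 0
    if zero6.any():
        warnings.warn(
            f"samples with zero omega-6 sum have undefined omega-3/omega-6 "
            f"ratio: {list(ratio.index[zero6])}",
            stacklevel=2,
        )
        ratio[zero6] = np.nan
    return ratio.rename("omega3_over_omega6")


def marker_values(
    table: FAProfileTable,
    overrides: Mapping[str, FAClass] = DEFAULT_CLASS_OVERRIDES,
) -> pd.DataFrame:
    """Copepod and bacterial diet markers per sample.

    Copepod marker: proportion of 20:1w11 (0 if absent from the table).
    Bacterial marker: summed proportion of all odd/branched-chain FA — by
    definition identical to the OBCFA class sum.
    """
    out = pd.DataFrame(index=table.values.index)
    if COPEPOD_MARKER in table.fa_labels:
        out["copepod_marker_pct"] = table.values[COPEPOD_MARKER]
    else:
        out["copepod_marker_pct"] = 0.0
    out["bacterial_sum_pct"] = class_sums(table, overrides)["obcfa_pct"]
    return out


def marker_summary(
    table: FAProfileTable,
    overrides: Mapping[str, FAClass] = DEFAULT_CLASS_OVERRIDES,
) -> pd.DataFrame:
    """All biomarker summaries in one per-sample DataFrame."""
    parts = [class_sums(table, overrides), omega_ratio(table).to_frame(),
             marker_values(table, overrides)]
    return pd.concat(parts, axis=1)
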