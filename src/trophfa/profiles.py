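"""FA profile tables: compositional samples × FA matrices with metadata.

A profile is the vector of all identified FA expressed as percent of total
(closure to 100).  The table couples that matrix with per-sample metadata
(role: consumer / food / wild, treatment, optional location and month) and
enforces closure on construction.  Raw GC peak areas are converted to
proportions here, with the unmethylated internal standard (19:0 by default)
excluded from the denominator and dropped from the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from trophfa.nomenclature import canonical_label

#: metadata columns recognised in wide CSV files, in canonical order
META_COLUMNS = ("sample", "role", "treatment", "location", "month")

#: incoming rows whose total differs from 100 by more than this many
#: percentage points trigger a warning before being re-closed
CLOSURE_WARN_TOL = 0.5

_CLOSURE_ATOL = 1e-6


class ProfileError(ValueError):
    """Raised for invalid profile data (negative values, all-zero rows, ...)."""


@dataclass
class FAProfileTable:
    """Samples × FA matrix of percent proportions with sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by sample id, columns FA labels, entries in percent.
        Rows are re-closed to sum to 100 on construction.
    meta : pandas.DataFrame
        Indexed like ``values``; columns ``role``, ``treatment`` and
        optionally ``location`` and ``month``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.values.index)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ProfileError(f"duplicate sample ids: {dups}")
        labels = [canonical_label(c) for c in self.values.columns]
        if len(set(labels)) != len(labels):
            raise ProfileError("duplicate FA labels after canonicalization")
        self.values = self.values.copy()
        self.values.columns = labels
        self.values = self.values.astype(float)
        if (self.values.values < 0).any():
            bad = self.values.index[(self.values.values < 0).any(axis=1)].tolist()
            raise ProfileError(f"negative proportions in samples {bad}")
        totals = self.values.sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ProfileError(f"all-zero profile rows for samples {bad}")
        off = (totals - 100.0).abs()
        if (off > CLOSURE_WARN_TOL).any():
            bad = off.index[off > CLOSURE_WARN_TOL].tolist()
            warnings.warn(
                f"profile rows for samples {bad} deviate from 100% by more than "
                f"{CLOSURE_WARN_TOL}; re-closing",
                stacklevel=2,
            )
        if (off > _CLOSURE_ATOL).any():
            self.values = self.values.div(totals, axis=0) * 100.0
        self.meta = self.meta.reindex(self.values.index)

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def fa_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset(self, mask) -> "FAProfileTable":
        """Row subset by boolean mask or list of sample ids."""
        if isinstance(mask, (list, tuple, pd.Index)):
            return FAProfileTable(self.values.loc[mask], self.meta.loc[mask])
        return FAProfileTable(self.values.loc[mask], self.meta.loc[mask])

    def by_treatment(self, treatment: str) -> "FAProfileTable":
        return self.subset(self.meta["treatment"] == treatment)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FAProfileTable):
            return NotImplemented
        return self.values.equals(other.values) and self.meta.fillna("").equals(
            other.meta.reindex(columns=self.meta.columns).fillna("")
        )


def peak_areas_to_proportions(
    areas: pd.DataFrame,
    excluded_labels: Iterable[str] = ("19:0",),
    meta: pd.DataFrame | None = None,
) -> FAProfileTable:
    """Convert raw chromatogram peak areas to percent-of-total proportions.

    Each row becomes ``100 * area_f / sum(non-excluded areas)``; excluded
    labels (by default the 19:0 internal standard) do not contribute to the
    denominator and are removed from the output table.

    Raises
    ------
    ProfileError
        For negative areas or a sample whose non-excluded areas are all zero.
    """
    areas = areas.copy()
    areas.columns = [canonical_label(c) for c in areas.columns]
    if (areas.values < 0).any():
        bad = areas.index[(areas.values < 0).any(axis=1)].tolist()
        raise ProfileError(f"negative peak areas in samples {bad}")
    excluded = {canonical_label(lab) for lab in excluded_labels}
    kept = [c for c in areas.columns if c not in excluded]
    if not kept:
        raise ProfileError("all FA columns excluded")
    sub = areas[kept]
    totals = sub.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ProfileError(f"samples with no non-excluded signal: {bad}")
    values = sub.div(totals, axis=0) * 100.0
    return FAProfileTable(values, meta)


def _split_meta_and_fa(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    meta_cols = [c for c in df.columns if c.lower() in META_COLUMNS]
    fa_cols = [c for c in df.columns if c.lower() not in META_COLUMNS]
    if not fa_cols:
        raise ProfileError("no FA columns found")
    meta = df[meta_cols].copy()
    meta.columns = [c.lower() for c in meta.columns]
    return meta, df[fa_cols]


def read_profile_table(path: str | Path, format: str = "wide_csv") -> FAProfileTable:
    """Read an FA profile table from CSV.

    ``wide_csv``: one row per sample; metadata columns (``sample``, ``role``,
    ``treatment``, ``location``, ``month`` — only ``sample`` required) followed
    by one column per FA.  ``long_csv``: columns ``sample``, metadata, ``fa``,
    ``value``.  FA labels are canonicalized on read; rows deviating from 100%
    by more than 0.5 points are re-closed with a warning.
    """
    df = pd.read_csv(path)
    if format == "wide_csv":
        meta, fa = _split_meta_and_fa(df)
    elif format == "long_csv":
        df.columns = [c.lower() for c in df.columns]
        required = {"sample", "fa", "value"}
        if not required <= set(df.columns):
            raise ProfileError(f"long format needs columns {sorted(required)}")
        df["sample"] = df["sample"].astype(str)
        values = df.pivot(index="sample", columns="fa", values="value")
        values = values.loc[df["sample"].drop_duplicates().values]  # original order
        meta_cols = [c for c in df.columns if c in META_COLUMNS and c != "sample"]
        meta = (
            df[["sample"] + meta_cols].drop_duplicates("sample").set_index("sample")
        ).reindex(values.index)
        values.columns.name = None
        values.index.name = None
        meta.index.name = None
        return FAProfileTable(values, meta)
    else:
        raise ValueError(f"unknown format {format!r}")
    if "sample" not in meta.columns:
        raise ProfileError("missing 'sample' column")
    sample_ids = meta["sample"].astype(str)
    if sample_ids.duplicated().any():
        raise ProfileError(f"duplicate sample ids: {sample_ids[sample_ids.duplicated()].tolist()}")
    values = fa.copy()
    values.index = sample_ids.values
    meta = meta.drop(columns=["sample"])
    meta.index = sample_ids.values
    return FAProfileTable(values, meta)


def write_profile_table(
    table: FAProfileTable, path: str | Path, format: str = "wide_csv"
) -> None:
    """Write a profile table to CSV in the wide or long dialect."""
    meta = table.meta.copy()
    meta.insert(0, "sample", table.values.index)
    if format == "wide_csv":
        out = pd.concat([meta.reset_index(drop=True),
                         table.values.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False, float_format="%.10g")
    elif format == "long_csv":
        long = table.values.stack().rename("value").reset_index()
        long.columns = ["sample", "fa", "value"]
        long = long.merge(meta, on="sample", how="left")
        cols = ["sample"] + [c for c in meta.columns if c != "sample"] + ["fa", "value"]
        long[cols].to_csv(path, index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown format {format!r}")


def concat_tables(tables: Sequence[FAProfileTable]) -> FAProfileTable:
    """Stack profile tables over samples, aligning FA columns (missing → 0)."""
    labels: list[str] = []
    for t in tables:
        for lab in t.fa_labels:
            if lab not in labels:
                labels.append(lab)
    vals = pd.concat([t.values.reindex(columns=labels, fill_value=0.0) for t in tables])
    meta = pd.concat([t.meta for t in tables])
    return FAProfileTable(vals, meta)
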