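"""Synthetic feeding-assay and wild-survey generators with known ground truth.

The generator emulates the structure of a juvenile-crab feeding assay: each
treatment has a food with its own mean FA composition; consumer profiles are
the food mean reweighted elementwise by a known vector of trophic-
modification coefficients and re-closed to 100%; replicates of both foods
and consumers are drawn from a Dirichlet distribution around their mean
composition, which respects closure and non-negativity.  Because of closure
the observable consumer/food ratio for FA *i* is ``c_i / Σ_j c_j f_j`` — a
constant multiple of the true coefficient within a treatment — so the
recoverable ground truth is the vector of coefficient *ratios*.

The default registry holds 42 FA with baseline proportions dominated by
16:0, 20:5w3, 18:0, 22:6w3 and 18:1w9 (together ~75% of the total), and
class sums of ~43% SFA, ~12% MUFA, ~35% PUFA and ~10% OBCFA — the profile
structure typical of a marine crustacean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trophfa.nomenclature import canonical_label, is_lcpufa
from trophfa.profiles import FAProfileTable

#: default within-treatment replicate dispersions (Dirichlet concentration).
#: Consumers: 2000 puts the replicate SD of a 14% FA at ~0.8 percentage
#: points, the magnitude reported for DHA replicates in laboratory-fed
#: crabs (14.3 ± 0.7%).  Foods: pellets are subsamples of one homogenized
#: stock and vary far less (DHA 14.3 ± 0.3% → concentration ≈ 13600).
DEFAULT_DISPERSION = 2000.0
DEFAULT_FOOD_DISPERSION = 13600.0

# (label, baseline percent) — 42 FA summing to 100 with class sums
# SFA 43.0 / MUFA 11.7 / PUFA 35.2 / OBCFA 10.0
_DEFAULT_REGISTRY: list[tuple[str, float]] = [
    # saturated
    ("16:0", 26.4), ("18:0", 13.2), ("14:0", 2.2), ("20:0", 0.5),
    ("22:0", 0.4), ("12:0", 0.2), ("24:0", 0.1),
    # monounsaturated
    ("18:1w9", 7.0), ("16:1w7", 2.2), ("20:1w11", 1.0), ("20:1w9", 0.6),
    ("22:1w11", 0.3), ("16:1w9", 0.3), ("24:1w9", 0.3),
    # polyunsaturated
    ("20:5w3", 16.6), ("22:6w3", 11.4), ("20:4w6", 2.2), ("18:2w6", 1.4),
    ("22:5w3", 1.2), ("18:3w3", 0.9), ("18:4w3", 0.5), ("20:2w6", 0.3),
    ("20:3w3", 0.2), ("22:4w6", 0.2), ("16:2w4", 0.25), ("16:4w3", 0.15),
    # odd / branched chain (bacterial markers, incl. 18:1w7)
    ("18:1w7", 3.0), ("15:0", 1.2), ("17:0", 1.0), ("i15:0", 0.9),
    ("a15:0", 0.8), ("i17:0", 0.6), ("a17:0", 0.5), ("i16:0", 0.4),
    ("17:1w8", 0.4), ("15:1w6", 0.2), ("19:1w8", 0.2), ("i14:0", 0.2),
    ("i18:0", 0.2), ("21:5w3", 0.2), ("23:0", 0.1), ("13:0", 0.1),
]


def default_registry() -> pd.DataFrame:
    """The default 42-FA registry: columns ``label`` and ``baseline_pct``."""
    df = pd.DataFrame(_DEFAULT_REGISTRY, columns=["label", "baseline_pct"])
    df["label"] = [canonical_label(lab) for lab in df["label"]]
    return df


def default_coefficients(registry: pd.DataFrame | None = None) -> pd.Series:
    """A coefficient vector mimicking the observed modification pattern.

    Abundant (≥1% baseline) long-chain PUFA except 22:5w3, plus 18:1w9 and
    18:1w7, are enriched in the consumer (coefficient > 1); everything else
    is mildly diluted.
    """
    reg = default_registry() if registry is None else registry
    coefs = {}
    for lab, base in zip(reg["label"], reg["baseline_pct"]):
        if lab in ("18:1w9", "18:1w7"):
            coefs[lab] = 1.6
        elif is_lcpufa(lab) and base >= 1.0 and lab != "22:5w3":
            coefs[lab] = 1.5
        elif lab == "22:5w3":
            coefs[lab] = 0.7
        else:
            coefs[lab] = 0.85
    return pd.Series(coefs)


@dataclass
class AssayConfig:
    """Configuration of a synthetic feeding assay.

    Attributes
    ----------
    registry : pandas.DataFrame
        Columns ``label`` and ``baseline_pct`` (summing to 100).
    treatments : list of (name, n_consumers, n_food_samples)
        Replicate design, e.g. five treatments of (5, 5).
    true_coefficients : mapping of treatment -> per-FA multiplier
        Defaults to :func:`default_coefficients` for every treatment.
    food_means : mapping of treatment -> per-FA mean percent, optional
        Fixes a treatment's food composition instead of perturbing the
        baseline (e.g. a bacteria-rich food with inflated OBCFA).
    dispersion : float
        Dirichlet concentration of the consumer replicate model; larger is
        less noisy.  ``inf`` gives noise-free replicates equal to the mean.
    food_dispersion : float
        Same for food replicates; much higher by default because food
        samples are subsamples of one homogenized stock.  ``None`` copies
        ``dispersion`` (a single-dial noise model).
    food_variation_sd : float
        Log-normal sigma of the per-treatment perturbation applied to the
        baseline composition to make foods differ between treatments.
    """

    registry: pd.DataFrame = field(default_factory=default_registry)
    treatments: Sequence[tuple[str, int, int]] = (
        ("bivalve", 5, 5), ("ghost_shrimp", 5, 5), ("mysid", 5, 5),
        ("megalopae", 5, 5), ("fish", 5, 5),
    )
    true_coefficients: Mapping[str, pd.Series] | None = None
    food_means: Mapping[str, pd.Series] | None = None
    dispersion: float = DEFAULT_DISPERSION
    food_dispersion: float | None = DEFAULT_FOOD_DISPERSION
    food_variation_sd: float = 0.3

    def __post_init__(self) -> None:
        if not np.isclose(self.registry["baseline_pct"].sum(), 100.0):
            raise ValueError("registry baseline proportions must sum to 100")
        if self.food_dispersion is None:
            self.food_dispersion = self.dispersion
        if self.dispersion <= 0 or self.food_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name, n_c, n_f in self.treatments:
            if n_c < 1 or n_f < 1:
                raise ValueError(f"treatment {name!r} needs at least one replicate of each role")

    def coefficients_for(self, treatment: str) -> pd.Series:
        labels = [canonical_label(lab) for lab in self.registry["label"]]
        if self.true_coefficients is not None and treatment in self.true_coefficients:
            c = pd.Series(self.true_coefficients[treatment]).reindex(labels)
            if c.isna().any() or (c <= 0).any():
                raise ValueError(f"coefficients for {treatment!r} must be positive and complete")
            return c
        return default_coefficients(self.registry).reindex(labels)


def _close(frac: np.ndarray) -> np.ndarray:
    return frac / frac.sum()


def _draw_rows(rng: np.random.Generator, mean_frac: np.ndarray,
               n: int, dispersion: float) -> np.ndarray:
    if np.isinf(dispersion):
        return np.tile(mean_frac, (n, 1)) * 100.0
    return rng.dirichlet(dispersion * mean_frac, size=n) * 100.0


def generate_assay(
    config: AssayConfig, seed: int
) -> tuple[FAProfileTable, FAProfileTable, dict]:
    """Generate (food_table, consumer_table, ground_truth) for one assay.

    Ground truth records, per treatment, the coefficient vector applied and
    the post-closure expected consumer/food ratios ``c_i / Σ_j c_j f_j``
    (what an estimator can actually recover).
    """
    rng = np.random.default_rng(seed)
    labels = [canonical_label(lab) for lab in config.registry["label"]]
    base = _close(config.registry["baseline_pct"].to_numpy(dtype=float))
    food_rows, cons_rows = [], []
    food_meta, cons_meta = [], []
    truth: dict = {"seed": seed, "dispersion": config.dispersion,
                   "food_dispersion": config.food_dispersion, "treatments": {}}
    for name, n_cons, n_food in config.treatments:
        if config.food_means is not None and name in config.food_means:
            fm = pd.Series(config.food_means[name]).reindex(labels)
            if fm.isna().any() or (fm < 0).any():
                raise ValueError(f"food mean for {name!r} must be non-negative and complete")
            food_mean = _close(fm.to_numpy(dtype=float))
            rng.lognormal(0.0, config.food_variation_sd, len(base))  # keep stream aligned
        else:
            food_mean = _close(base * rng.lognormal(0.0, config.food_variation_sd, len(base)))
        c = config.coefficients_for(name).to_numpy(dtype=float)
        cons_mean = _close(food_mean * c)
        food = _draw_rows(rng, food_mean, n_food, config.food_dispersion)
        cons = _draw_rows(rng, cons_mean, n_cons, config.dispersion)
        food_rows.append(food)
        cons_rows.append(cons)
        food_meta += [{"role": "food", "treatment": name} for _ in range(n_food)]
        cons_meta += [{"role": "consumer", "treatment": name} for _ in range(n_cons)]
        truth["treatments"][name] = {
            "coefficients": dict(zip(labels, map(float, c))),
            "expected_ratios": dict(zip(labels, map(float, cons_mean / food_mean))),
            "food_mean_pct": dict(zip(labels, map(float, food_mean * 100))),
        }
    food_ids = [f"{m['treatment']}_food_{i + 1}"
                for i, m in zip(_within_counter(food_meta), food_meta)]
    cons_ids = [f"{m['treatment']}_crab_{i + 1}"
                for i, m in zip(_within_counter(cons_meta), cons_meta)]
    food_table = FAProfileTable(
        pd.DataFrame(np.vstack(food_rows), index=food_ids, columns=labels),
        pd.DataFrame(food_meta, index=food_ids),
    )
    consumer_table = FAProfileTable(
        pd.DataFrame(np.vstack(cons_rows), index=cons_ids, columns=labels),
        pd.DataFrame(cons_meta, index=cons_ids),
    )
    return food_table, consumer_table, truth


def _within_counter(meta: list[dict]) -> list[int]:
    counts: dict[str, int] = {}
    out = []
    for m in meta:
        counts[m["treatment"]] = counts.get(m["treatment"], 0) + 1
        out.append(counts[m["treatment"]] - 1)
    return out


def generate_wild_design(
    seed: int,
    locations: Sequence[str] = ("Crown Point", "Valino Island", "Sengstacken"),
    months: Sequence[str] = ("July", "September"),
    n_per_cell: int = 4,
    location_effects: Mapping[str, Mapping[str, float]] | None = None,
    month_effects: Mapping[str, Mapping[str, float]] | None = None,
    interaction_effects: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
    dispersion: float = DEFAULT_DISPERSION,
    registry: pd.DataFrame | None = None,
) -> FAProfileTable:
    """Factorial wild-survey data (locations × months, n per cell).

    Effects are multiplicative per-FA perturbations of the baseline mean
    composition, keyed by level (or level pair for the interaction); with no
    effects every cell shares one mean and the design is exchangeable, which
    is the configuration used for type-I-error checks.
    """
    rng = np.random.default_rng(seed)
    reg = default_registry() if registry is None else registry
    labels = [canonical_label(lab) for lab in reg["label"]]
    base = _close(reg["baseline_pct"].to_numpy(dtype=float))
    rows, meta, ids = [], [], []
    for loc in locations:
        for month in months:
            mult = np.ones(len(base))
            for effects, key in (
                (location_effects, loc),
                (month_effects, month),
                (interaction_effects, (loc, month)),
            ):
                if effects and key in effects:
                    for lab, m in effects[key].items():
                        mult[labels.index(canonical_label(lab))] *= m
            mean = _close(base * mult)
            cell = _draw_rows(rng, mean, n_per_cell, dispersion)
            rows.append(cell)
            for i in range(n_per_cell):
                ids.append(f"{loc.replace(' ', '')}_{month}_{i + 1}")
                meta.append({"role": "wild", "treatment": f"{loc}/{month}",
                             "location": loc, "month": month})
    return FAProfileTable(
        pd.DataFrame(np.vstack(rows), index=ids, columns=labels),
        pd.DataFrame(meta, index=ids),
    )
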