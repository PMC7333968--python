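"""Permutational MANOVA, NMDS ordination, and centroid-shift vectors.

PERMANOVA partitions the total sum of squared inter-point distances among
experimental factors and tests each term with a pseudo-F statistic against a
permutation null (unrestricted permutation of raw observations).  For
Euclidean distances on univariate data the pseudo-F is algebraically equal
to the classical ANOVA F, which this implementation exploits as a
cross-check.  The two-way crossed design uses type-III (marginal) sums of
squares obtained from hat-matrix projections of the Gower-centered
inner-product matrix.

NMDS embeds a distance matrix in k dimensions preserving rank order of the
distances, minimizing Kruskal stress-1 by iterative majorization (SMACOF)
with primary-tie isotonic regression of the disparities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import factorial
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from sympy.utilities.iterables import multiset_permutations


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

def euclidean_distances(matrix: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample rows.

    Raises on missing values: compositional closure leaves no holes, so a
    NaN indicates an upstream data problem rather than something to impute.
    """
    if isinstance(matrix, pd.DataFrame):
        ids = [str(i) for i in matrix.index]
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(arr.shape[0])]
    if np.isnan(arr).any():
        raise ValueError(
            "missing values in the data matrix; re-close the composition "
            "upstream rather than imputing distances"
        )
    return DistanceMatrix(squareform(pdist(arr, metric="euclidean")), ids=ids)


def _as_square(d) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, DistanceMatrix):
        return d.data.copy(), list(d.ids)
    arr = np.asarray(d, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

@dataclass
class PermanovaTerm:
    name: str
    df: int
    ss: float
    ms: float
    pseudo_f: float
    p_perm: float
    n_unique_perms: int


@dataclass
class PermanovaResult:
    """ANOVA-style partition of multivariate variation.

    ``terms`` holds one entry per tested factor; ``residual_*`` and
    ``total_ss`` complete the partition (term dfs + residual df = n - 1).
    """

    terms: list[PermanovaTerm]
    residual_df: int
    residual_ss: float
    residual_ms: float
    total_ss: float
    n_samples: int
    n_permutations: int
    seed: int | None = None
    exact: bool = False

    @property
    def pseudo_f(self) -> float:
        """Pseudo-F of the first (or only) term — convenience for one-way use."""
        return self.terms[0].pseudo_f

    @property
    def p_value(self) -> float:
        return self.terms[0].p_perm

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "df": t.df, "MS": t.ms, "pseudo_F": t.pseudo_f,
             "p_perm": t.p_perm, "unique_perms": t.n_unique_perms}
            for t in self.terms
        ]
        rows.append({"term": "residual", "df": self.residual_df,
                     "MS": self.residual_ms, "pseudo_F": np.nan,
                     "p_perm": np.nan, "unique_perms": np.nan})
        return pd.DataFrame(rows)


def _grouping_to_codes(grouping, ids: list[str]) -> tuple[np.ndarray, list]:
    if isinstance(grouping, pd.Series):
        grouping = grouping.reindex(ids) if set(map(str, grouping.index)) >= set(ids) else grouping
        values = np.asarray(grouping)
    else:
        values = np.asarray(list(grouping))
    if len(values) != len(ids):
        raise ValueError("grouping length does not match distance matrix")
    levels = list(dict.fromkeys(values.tolist()))
    codes = np.array([levels.index(v) for v in values])
    return codes, levels


def _oneway_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_total - ss_within, ss_within


def _oneway_f(d2: np.ndarray, codes: np.ndarray, n_groups: int,
              df_a: int, df_w: int) -> float:
    ss_among, ss_within = _oneway_ss(d2, codes, n_groups)
    if ss_within <= 0:
        return math.inf if ss_among > 0 else math.nan
    return (ss_among / df_a) / (ss_within / df_w)


def _n_distinct_relabelings(counts: np.ndarray) -> float:
    num = factorial(counts.sum(), exact=True)
    for c in counts:
        num //= factorial(c, exact=True)
    return num


def permanova_oneway(
    d,
    grouping,
    n_perm: int = 9999,
    seed: int | None = None,
    return_permuted: bool = False,
):
    """One-way PERMANOVA from a distance matrix.

    Sums of squares follow the inter-point-distance identities
    ``SS_total = (1/n) Σ_{i<j} d²`` and ``SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²``;
    pseudo-F is the ratio of among/within mean squares.  The p-value is
    ``(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`` over random relabelings;
    when the number of distinct relabelings is at most ``n_perm`` the
    null set is enumerated exactly and the exact p reported.

    ``seed`` is required whenever random sampling is used.
    """
    dmat, ids = _as_square(d)
    d2 = dmat ** 2
    codes, levels = _grouping_to_codes(grouping, ids)
    a = len(levels)
    if a < 2:
        raise ValueError("need at least two groups")
    n = len(codes)
    counts = np.bincount(codes, minlength=a)
    df_a, df_w = a - 1, n - a
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    f_obs = _oneway_f(d2, codes, a, df_a, df_w)
    ss_among, ss_within = _oneway_ss(d2, codes, a)
    ss_total = ss_among + ss_within

    n_distinct = _n_distinct_relabelings(counts)
    tol = 1e-12 * max(1.0, abs(f_obs)) if math.isfinite(f_obs) else 0.0
    perm_fs = []
    if n_distinct <= n_perm:
        for lab in multiset_permutations(codes.tolist()):
            perm_fs.append(_oneway_f(d2, np.asarray(lab), a, df_a, df_w))
        perm_fs = np.asarray(perm_fs)
        count = int(np.sum(perm_fs >= f_obs - tol))
        p = count / len(perm_fs)
        n_unique = len(perm_fs)
        exact = True
    else:
        if seed is None:
            raise ValueError("seed is required for sampled permutations")
        rng = np.random.default_rng(seed)
        seen = set()
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            perm_fs.append(_oneway_f(d2, perm, a, df_a, df_w))
            seen.add(perm.tobytes())
        perm_fs = np.asarray(perm_fs)
        count = int(np.sum(perm_fs >= f_obs - tol))
        p = (1 + count) / (1 + n_perm)
        n_unique = len(seen)
        exact = False

    term = PermanovaTerm("groups", df_a, ss_among, ss_among / df_a, f_obs, p, n_unique)
    result = PermanovaResult(
        terms=[term],
        residual_df=df_w,
        residual_ss=ss_within,
        residual_ms=ss_within / df_w if df_w else math.nan,
        total_ss=ss_total,
        n_samples=n,
        n_permutations=len(perm_fs),
        seed=seed,
        exact=exact,
    )
    if return_permuted:
        return result, perm_fs
    return result


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _effects_design(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (effects) coding, n × (levels-1)."""
    x = np.zeros((codes.size, n_levels - 1))
    for j in range(n_levels - 1):
        x[codes == j, j] = 1.0
    x[codes == n_levels - 1, :] = -1.0
    return x


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova_twoway(
    d,
    factor_a,
    factor_b,
    n_perm: int = 9999,
    seed: int | None = None,
    names: tuple[str, str] = ("A", "B"),
):
    """Two-way crossed PERMANOVA with type-III sums of squares.

    Each term's SS is ``tr((H_full − H_without_term) G)`` where ``G`` is the
    Gower-centered inner-product matrix and the hat matrices come from a
    sum-to-zero-coded model matrix, so main effects are tested marginally to
    everything else (type III; identical to the sequential partition in
    balanced designs).  Terms are tested against the residual MS under
    unrestricted permutation of raw observations.

    Empty cells make marginal main-effect tests undefined and raise — unless
    the interaction is fully aliased with the main effects (one factor a pure
    replicate of the other), in which case the interaction SS is 0 and the
    remaining terms are still well defined.
    """
    dmat, ids = _as_square(d)
    d2 = dmat ** 2
    ca, la = _grouping_to_codes(factor_a, ids)
    cb, lb = _grouping_to_codes(factor_b, ids)
    n = len(ca)
    a_lev, b_lev = len(la), len(lb)
    xa = _effects_design(ca, a_lev)
    xb = _effects_design(cb, b_lev)
    xab = np.concatenate(
        [xa[:, [i]] * xb[:, [j]] for i in range(xa.shape[1]) for j in range(xb.shape[1])],
        axis=1,
    )
    ones = np.ones((n, 1))
    x_full = np.hstack([ones, xa, xb, xab])
    x_mains = np.hstack([ones, xa, xb])
    rank_full = np.linalg.matrix_rank(x_full)
    cell_counts = pd.crosstab(pd.Series(ca), pd.Series(cb)).reindex(
        index=range(a_lev), columns=range(b_lev), fill_value=0
    )
    occupied = cell_counts.values > 0
    # fully confounded factors (one a pure replicate of the other) keep the
    # remaining terms well defined; any other empty-cell pattern does not
    fully_confounded = (
        (occupied.sum(axis=1) == 1).all() and (occupied.sum(axis=0) == 1).all()
    )
    if (~occupied).any() and not fully_confounded:
        raise ValueError(
            "empty cells in the crossed design: type-III sums of squares undefined"
        )

    g = _gower_center(d2)
    h_full = _hat(x_full)
    term_specs = [
        (names[0], np.hstack([ones, xb, xab])),
        (names[1], np.hstack([ones, xa, xab])),
        (f"{names[0]} x {names[1]}", x_mains),
    ]
    h_reduced = {name: _hat(x_red) for name, x_red in term_specs}
    df_terms = {
        name: rank_full - np.linalg.matrix_rank(x_red) for name, x_red in term_specs
    }
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    resid_proj = np.eye(n) - h_full

    def term_stats(gmat: np.ndarray) -> tuple[dict[str, float], float]:
        ss_res = float(np.sum(resid_proj * gmat))
        ss = {name: float(np.sum((h_full - h_reduced[name]) * gmat))
              for name, _ in term_specs}
        return ss, ss_res

    ss_obs, ss_res_obs = term_stats(g)
    ms_res = ss_res_obs / df_res

    def f_of(ss: float, df: int, ss_res: float) -> float:
        if df == 0:
            return math.nan
        if ss_res <= 0:
            return math.inf if ss > 0 else math.nan
        return (ss / df) / (ss_res / df_res)

    f_obs = {name: f_of(ss_obs[name], df_terms[name], ss_res_obs)
             for name, _ in term_specs}

    if seed is None:
        raise ValueError("seed is required for sampled permutations")
    rng = np.random.default_rng(seed)
    counts = {name: 0 for name, _ in term_specs}
    seen = set()
    for _ in range(n_perm):
        perm = rng.permutation(n)
        seen.add(perm.tobytes())
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = term_stats(gp)
        for name, _ in term_specs:
            fp = f_of(ss_p[name], df_terms[name], ss_res_p)
            fo = f_obs[name]
            if math.isfinite(fo):
                if fp >= fo - 1e-12 * max(1.0, abs(fo)):
                    counts[name] += 1
            elif math.isinf(fo) and math.isinf(fp):
                counts[name] += 1
    n_unique = len(seen)

    terms = []
    for name, _ in term_specs:
        df_t = df_terms[name]
        p = (1 + counts[name]) / (1 + n_perm) if df_t > 0 else math.nan
        terms.append(
            PermanovaTerm(
                name=name,
                df=df_t,
                ss=ss_obs[name],
                ms=ss_obs[name] / df_t if df_t else math.nan,
                pseudo_f=f_obs[name],
                p_perm=p,
                n_unique_perms=n_unique,
            )
        )
    ss_total = float(np.trace(g))
    return PermanovaResult(
        terms=terms,
        residual_df=df_res,
        residual_ss=ss_res_obs,
        residual_ms=ms_res,
        total_ss=ss_total,
        n_samples=n,
        n_permutations=n_perm,
        seed=seed,
        exact=False,
    )


def pairwise_permanova(
    d,
    grouping,
    n_perm: int = 9999,
    seed: int | None = None,
    monte_carlo: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Post-hoc pairwise comparisons between all group pairs.

    For each pair, ``t = sqrt(pseudo-F)`` from a one-way PERMANOVA restricted
    to that pair, with a permutation p (exact when few distinct relabelings
    exist).  With ``monte_carlo=True`` an additional Monte-Carlo p is drawn
    by resampling 10 000 permuted t values with replacement and taking the
    continuity-corrected tail proportion — useful when the exact permutation
    set is too small to resolve small p-values.  No multiplicity adjustment
    by default; ``holm=True`` adds Holm-adjusted columns.
    """
    dmat, ids = _as_square(d)
    codes, levels = _grouping_to_codes(grouping, ids)
    rng = np.random.default_rng(seed) if seed is not None else None
    rows = []
    for (i, gi), (j, gj) in combinations(enumerate(levels), 2):
        idx = np.flatnonzero((codes == i) | (codes == j))
        sub = dmat[np.ix_(idx, idx)]
        sub_groups = [levels[codes[s]] for s in idx]
        n_i = int(np.sum(codes == i))
        n_j = int(np.sum(codes == j))
        if min(n_i, n_j) < 1 or n_i + n_j < 3:
            raise ValueError(f"pair ({gi}, {gj}) too small to compare")
        singleton = min(n_i, n_j) == 1
        res, perm_fs = permanova_oneway(
            sub, sub_groups, n_perm=n_perm, seed=seed, return_permuted=True
        )
        f = res.pseudo_f
        t = math.sqrt(f) if math.isfinite(f) and f >= 0 else math.inf
        p_perm = math.nan if singleton else res.p_value
        row = {
            "group_1": gi, "group_2": gj, "t": t, "p_perm": p_perm,
            "n_unique_perms": res.terms[0].n_unique_perms,
        }
        if monte_carlo:
            if rng is None:
                raise ValueError("seed is required for Monte-Carlo p-values")
            with np.errstate(invalid="ignore"):
                perm_t = np.sqrt(np.clip(perm_fs[np.isfinite(perm_fs)], 0, None))
            if perm_t.size == 0:
                row["p_mc"] = math.nan
            else:
                draws = rng.choice(perm_t, size=10_000, replace=True)
                row["p_mc"] = (1 + int(np.sum(draws >= t))) / (1 + 10_000)
        rows.append(row)
    out = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        mask = out["p_perm"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.values] = multipletests(out.loc[mask, "p_perm"], method="holm")[1]
        out["p_perm_holm"] = adj
    return out


# --------------------------------------------------------------------------
# NMDS
# --------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """An NMDS configuration with its Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool
    n_iter: int
    seed: int | None = None
    stress_trace: list[float] = field(default_factory=list)


def _classical_mds(dmat: np.ndarray, k: int) -> np.ndarray:
    g = _gower_center(dmat ** 2)
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(w)


def _monotone_disparities(dvec: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Primary-tie (weak) isotonic disparities of configuration distances."""
    order = np.lexsort((dist, dvec))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(order.size), dist[order])
    out = np.empty_like(dist)
    out[order] = fitted
    return out


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float(np.sum(dist ** 2))
    if denom == 0:
        return 0.0
    return math.sqrt(float(np.sum((dist - disp) ** 2)) / denom)


def _smacof_single(
    dvec: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, int, list[float]]:
    n = x0.shape[0]
    x = x0 - x0.mean(axis=0)
    trace: list[float] = []
    stress_prev = math.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dist = pdist(x)
        disp = _monotone_disparities(dvec, dist)
        stress = _stress1(dist, disp)
        trace.append(stress)
        if stress_prev - stress < tol:
            converged = True
            break
        stress_prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / dist, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
    return x, trace[-1], converged, it, trace


def nmds(
    d,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling by majorization (SMACOF).

    Runs one metric-scaling (classical MDS) start plus ``n_starts`` random
    starts and keeps the configuration with the lowest Kruskal stress-1.
    The returned configuration is centered and rotated to its principal
    axes.  ``converged=False`` means no start met the stress-change
    tolerance within ``max_iter`` iterations (the best configuration is
    still returned).
    """
    dmat, ids = _as_square(d)
    n = dmat.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for a {k}-dimensional embedding")
    if n_starts > 0 and seed is None:
        raise ValueError("seed is required for random starts")
    dvec = squareform(dmat, checks=False)
    starts = [_classical_mds(dmat, k)]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        starts.append(rng.normal(size=(n, k)))
    best = None
    for x0 in starts:
        x, stress, conv, n_iter, trace = _smacof_single(dvec, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, conv, n_iter, trace)
    x, stress, conv, n_iter, trace = best
    # rotate to principal axes
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    coords = pd.DataFrame(x, index=ids, columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(coords, stress, conv, n_iter, seed, trace)


# --------------------------------------------------------------------------
# centroid shifts
# --------------------------------------------------------------------------

def centroid_shifts(
    coordinates: pd.DataFrame,
    grouping,
    pairing: Mapping[str, str],
) -> pd.DataFrame:
    """Food→consumer centroid vectors in a coordinate space.

    ``coordinates`` may be an ordination configuration (display space) or the
    full transformed-FA matrix (ordination-free).  ``pairing`` maps each
    consumer group to its food group; the vector points from the food
    centroid to the consumer centroid and ``magnitude`` is its Euclidean
    norm.
    """
    groups = pd.Series(list(grouping), index=coordinates.index)
    rows = []
    for consumer, food in pairing.items():
        gc = coordinates[groups == consumer]
        gf = coordinates[groups == food]
        if gc.empty or gf.empty:
            raise ValueError(f"empty group in pairing ({consumer!r}, {food!r})")
        vec = gc.mean(axis=0) - gf.mean(axis=0)
        row = {"consumer": consumer, "food": food,
               "magnitude": float(np.linalg.norm(vec))}
        for dim, val in vec.items():
            row[f"shift_{dim}"] = float(val)
        rows.append(row)
    return pd.DataFrame(rows)
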