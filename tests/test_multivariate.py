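import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import permanova as skbio_permanova

from trophfa.markers import arcsine_sqrt_transform
from trophfa.multivariate import (
    centroid_shifts,
    euclidean_distances,
    nmds,
    pairwise_permanova,
    permanova_oneway,
    permanova_twoway,
)
from trophfa.synthetic import generate_wild_design


def brute_force_p(d: np.ndarray, groups: list) -> float:
    """Independent oracle: enumerate every ordering of the group labels."""
    obs = _f_from_labels(d, groups)
    count = total = 0
    for perm in itertools.permutations(groups):
        f = _f_from_labels(d, list(perm))
        total += 1
        if f >= obs - 1e-12 * max(1.0, abs(obs)):
            count += 1
    return count / total


def _f_from_labels(d: np.ndarray, labels: list) -> float:
    labels = np.asarray(labels)
    d2 = d ** 2
    n = len(labels)
    groups = np.unique(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    ss_among = ss_total - ss_within
    return (ss_among / (len(groups) - 1)) / (ss_within / (n - len(groups)))


class TestDistances:
    def test_identical_rows_distance_zero(self):
        dm = euclidean_distances(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert dm.data[0, 1] == 0.0

    def test_three_four_five(self):
        dm = euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert dm.data[0, 1] == pytest.approx(5.0)

    def test_triangle_inequality(self, rng):
        x = rng.normal(size=(6, 4))
        d = euclidean_distances(x).data
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            euclidean_distances(np.array([[0.0, np.nan], [1.0, 2.0]]))


class TestOnewayPermanova:
    def test_toy_example_f8_exact_third(self):
        d = squareform(pdist(np.array([[0.0], [1.0], [2.0], [3.0]])))
        res = permanova_oneway(d, ["a", "a", "b", "b"])
        assert res.pseudo_f == pytest.approx(8.0)
        assert res.p_value == pytest.approx(1 / 3)
        assert res.exact

    def test_pseudo_f_equals_classical_anova_f(self, rng):
        for _ in range(10):
            sizes = rng.integers(3, 7, size=rng.integers(2, 5))
            groups = np.repeat(np.arange(sizes.size), sizes)
            y = rng.normal(size=groups.size)
            d = squareform(pdist(y[:, None]))
            res = permanova_oneway(d, groups.tolist(), n_perm=99, seed=0)
            f_classic = stats.f_oneway(*[y[groups == g] for g in np.unique(groups)]).statistic
            assert res.pseudo_f == pytest.approx(f_classic, rel=1e-9)

    def test_matches_skbio_pseudo_f(self, rng):
        x = rng.normal(size=(15, 6))
        groups = (["a"] * 5) + (["b"] * 5) + (["c"] * 5)
        dm = euclidean_distances(x)
        ours = permanova_oneway(dm, groups, n_perm=99, seed=1)
        theirs = skbio_permanova(dm, grouping=groups, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_exact_p_equals_brute_force_enumeration(self, rng):
        y = rng.normal(size=7)
        d = squareform(pdist(y[:, None]))
        groups = ["a", "a", "a", "b", "b", "b", "b"]
        res = permanova_oneway(d, groups)
        assert res.exact and res.terms[0].n_unique_perms == math.comb(7, 3)
        assert res.p_value == pytest.approx(brute_force_p(d, groups), abs=1e-12)

    def test_sampled_p_consistent_with_exact(self, rng):
        y = rng.normal(size=8)
        d = squareform(pdist(y[:, None]))
        groups = ["a"] * 4 + ["b"] * 4
        exact = permanova_oneway(d, groups).p_value
        sampled = permanova_oneway(d, groups, n_perm=50, seed=5).p_value
        assert abs(sampled - exact) < 0.2

    def test_ss_conservation(self, rng):
        x = rng.normal(size=(12, 5))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = permanova_oneway(euclidean_distances(x), groups, n_perm=9, seed=0)
        assert res.terms[0].ss + res.residual_ss == pytest.approx(res.total_ss, rel=1e-9)

    def test_permutation_invariance_of_f(self, rng):
        x = rng.normal(size=(9, 3))
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        d = squareform(pdist(x))
        f1 = permanova_oneway(d, groups.tolist(), n_perm=9, seed=0).pseudo_f
        order = rng.permutation(9)
        f2 = permanova_oneway(d[np.ix_(order, order)], groups[order].tolist(),
                              n_perm=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_zero_within_variance_reports_inf(self):
        d = squareform(pdist(np.array([[0.0], [0.0], [1.0], [1.0]])))
        res = permanova_oneway(d, ["a", "a", "b", "b"])
        assert math.isinf(res.pseudo_f)
        assert 0 < res.p_value <= 1


class TestTwowayPermanova:
    def test_balanced_univariate_matches_classical_anova(self, rng):
        # 2x3 balanced design, n=3 per cell
        a = np.repeat(["a1", "a2"], 9)
        b = np.tile(np.repeat(["b1", "b2", "b3"], 3), 2)
        y = rng.normal(size=18)
        d = squareform(pdist(y[:, None]))
        res = permanova_twoway(d, a.tolist(), b.tolist(), n_perm=49, seed=0)
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.DataFrame({"y": y, "a": a, "b": b})
        classic = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", df).fit(), typ=2)
        for term, row_name in [(res.terms[0], "C(a)"), (res.terms[1], "C(b)"),
                               (res.terms[2], "C(a):C(b)")]:
            assert term.ss == pytest.approx(classic.loc[row_name, "sum_sq"], rel=1e-9)
            assert term.pseudo_f == pytest.approx(classic.loc[row_name, "F"], rel=1e-9)
        assert res.residual_ss == pytest.approx(classic.loc["Residual", "sum_sq"], rel=1e-9)

    def test_wild_design_degrees_of_freedom(self):
        table = generate_wild_design(seed=3)
        dm = euclidean_distances(arcsine_sqrt_transform(table))
        res = permanova_twoway(dm, table.meta["location"].values, table.meta["month"].values,
                               n_perm=49, seed=0, names=("location", "month"))
        assert [t.df for t in res.terms] == [2, 1, 2]
        assert res.residual_df == 18
        assert sum(t.df for t in res.terms) + res.residual_df == res.n_samples - 1

    def test_aliased_factor_gives_zero_interaction_ss(self, rng):
        a = ["a1"] * 4 + ["a2"] * 4
        b = ["b1"] * 4 + ["b2"] * 4  # pure replicate of a
        y = rng.normal(size=(8, 3))
        res = permanova_twoway(euclidean_distances(y), a, b, n_perm=19, seed=0)
        assert res.terms[2].ss == pytest.approx(0.0, abs=1e-9)
        assert res.terms[2].df == 0

    def test_genuinely_empty_cell_rejected(self, rng):
        a = ["a1", "a1", "a2", "a2", "a1", "a2"]
        b = ["b1", "b1", "b2", "b2", "b2", "b1"]
        # remove all (a2, b1)/(a1, b2)? construct a missing cell instead:
        a = ["a1"] * 3 + ["a2"] * 3 + ["a1"] * 2
        b = ["b1"] * 3 + ["b1"] * 3 + ["b2"] * 2  # cell (a2, b2) empty
        y = rng.normal(size=(8, 2))
        with pytest.raises(ValueError, match="empty cells"):
            permanova_twoway(euclidean_distances(y), a, b, n_perm=9, seed=0)

    def test_null_p_values_not_extreme(self, rng):
        table = generate_wild_design(seed=12)  # zero effects: exchangeable
        dm = euclidean_distances(arcsine_sqrt_transform(table))
        res = permanova_twoway(dm, table.meta["location"].values, table.meta["month"].values,
                               n_perm=199, seed=4)
        for t in res.terms:
            assert t.p_perm > 0.01


class TestPairwise:
    def test_row_count_is_choose_2(self, rng):
        x = rng.normal(size=(12, 3))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3
        out = pairwise_permanova(euclidean_distances(x), groups, n_perm=19, seed=0)
        assert len(out) == 6

    def test_t_is_sqrt_of_pair_pseudo_f(self):
        d = squareform(pdist(np.array([[0.0], [1.0], [2.0], [3.0]])))
        out = pairwise_permanova(d, ["a", "a", "b", "b"], n_perm=19, seed=0)
        assert out.loc[0, "t"] == pytest.approx(math.sqrt(8.0))

    def test_identical_groups_not_separable(self, rng):
        base = rng.normal(size=(4, 3))
        x = np.vstack([base, base])
        groups = ["a"] * 4 + ["b"] * 4
        out = pairwise_permanova(euclidean_distances(x), groups, n_perm=99, seed=0)
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-6)
        assert out.loc[0, "p_perm"] > 0.05

    def test_monte_carlo_and_holm_columns(self, rng):
        x = rng.normal(size=(9, 3))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        out = pairwise_permanova(euclidean_distances(x), groups, n_perm=99, seed=2,
                                 monte_carlo=True, holm=True)
        assert {"p_mc", "p_perm_holm"} <= set(out.columns)
        assert ((0 < out["p_mc"]) & (out["p_mc"] <= 1)).all()
        assert (out["p_perm_holm"] >= out["p_perm"] - 1e-12).all()


class TestNmds:
    def test_three_points_embed_perfectly(self):
        d = squareform(pdist(np.array([[0.0], [1.0], [5.0]])))
        res = nmds(d, k=2, seed=0)
        assert res.stress < 1e-6

    def test_recovers_known_2d_configuration(self, rng):
        x = rng.normal(size=(20, 2))
        res = nmds(euclidean_distances(x), k=2, seed=1)
        assert res.stress < 0.01
        _, _, disparity = procrustes(x, res.coordinates.values)
        assert disparity < 1e-3

    def test_stress_non_increasing_within_start(self, rng):
        x = rng.normal(size=(15, 5))
        res = nmds(euclidean_distances(x), k=2, seed=2)
        trace = np.array(res.stress_trace)
        assert (np.diff(trace) <= 1e-8).all()

    def test_configuration_is_centered(self, rng):
        x = rng.normal(size=(10, 4))
        res = nmds(euclidean_distances(x), k=2, seed=3)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_seed_required_for_random_starts(self, rng):
        d = euclidean_distances(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError, match="seed"):
            nmds(d, k=2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((2, 2)), k=2, seed=0)


class TestCentroidShifts:
    def test_identical_groups_zero_magnitude(self):
        coords = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0], "y": [0.0, 0.0, 0.0, 0.0]},
                              index=list("abcd"))
        out = centroid_shifts(coords, ["c", "c", "f", "f"], {"c": "f"})
        assert out.loc[0, "magnitude"] == pytest.approx(0.0)

    def test_pure_translation_recovered(self, rng):
        cloud = rng.normal(size=(5, 2))
        coords = pd.DataFrame(np.vstack([cloud + [1.0, 0.0], cloud]),
                              index=[f"s{i}" for i in range(10)], columns=["x", "y"])
        out = centroid_shifts(coords, ["c"] * 5 + ["f"] * 5, {"c": "f"})
        assert out.loc[0, "shift_x"] == pytest.approx(1.0, abs=1e-9)
        assert out.loc[0, "shift_y"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc[0, "magnitude"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self):
        coords = pd.DataFrame({"x": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            centroid_shifts(coords, ["c", "c"], {"c": "f"})
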