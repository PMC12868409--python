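"""Bray-Curtis, NMDS, PERMANOVA, and the year-segmentation tree."""

import numpy as np
import pandas as pd
import pytest

from saprocom.composition import (bray_curtis, inference_tree, nmds,
                                  permanova)


def sites_frame(X, labels=None):
    labels = labels or [f"site{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=labels,
                        columns=[f"sp{j}" for j in range(X.shape[1])])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = sites_frame(np.array([[1, 2, 3], [1, 2, 3]], float))
        D = bray_curtis(m)
        assert D.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        m = sites_frame(np.array([[5, 0, 0], [0, 3, 2]], float))
        assert bray_curtis(m).iloc[0, 1] == pytest.approx(1.0)

    def test_worked_example_five_sevenths(self):
        m = sites_frame(np.array([[2, 1, 0], [0, 1, 3]], float))
        assert bray_curtis(m).iloc[0, 1] == pytest.approx(5.0 / 7.0)

    def test_invariant_to_species_permutation(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 10, size=(6, 8)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        perm = rng.permutation(8)
        D1 = bray_curtis(sites_frame(X)).to_numpy()
        D2 = bray_curtis(sites_frame(X[:, perm])).to_numpy()
        np.testing.assert_allclose(D1, D2, atol=1e-12)

    def test_all_zero_row_rejected(self):
        m = sites_frame(np.array([[0, 0, 0], [1, 2, 3]], float))
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(m)


class TestNMDS:
    def test_recovers_noiseless_gradient(self):
        """1-D gradient dissimilarities: low stress, order preserved."""
        n = 12
        ranks = np.arange(n, dtype=float)
        D = np.abs(ranks[:, None] - ranks[None, :]) / (n - 1)
        res = nmds(sites_frame(D).rename(columns=dict(
            zip([f"sp{j}" for j in range(n)], [f"site{i}" for i in range(n)]))),
            k=2, n_starts=8, seed=0)
        assert res.stress < 0.05
        axis1 = res.scores["axis1"].to_numpy()
        order = np.argsort(axis1)
        assert (order == np.arange(n)).all() or (order == np.arange(n)[::-1]).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.2, 1, size=(8, 8))
        D = (X + X.T) / 2
        np.fill_diagonal(D, 0)
        df = pd.DataFrame(D, index=[f"s{i}" for i in range(8)],
                          columns=[f"s{i}" for i in range(8)])
        r1 = nmds(df, n_starts=4, seed=3)
        r2 = nmds(df, n_starts=4, seed=3)
        assert r1.stress == pytest.approx(r2.stress)
        np.testing.assert_allclose(r1.scores, r2.scores)

    def test_axis1_carries_most_variance(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.2, 1, size=(10, 10))
        D = (X + X.T) / 2
        np.fill_diagonal(D, 0)
        df = pd.DataFrame(D, index=[f"s{i}" for i in range(10)],
                          columns=[f"s{i}" for i in range(10)])
        res = nmds(df, k=2, n_starts=4, seed=4)
        v = res.scores.var(axis=0)
        assert v["axis1"] >= v["axis2"]


def _balanced_factors(n_groups, n_per):
    return pd.Series([f"g{i}" for i in range(n_groups) for _ in range(n_per)])


class TestPermanova:
    def test_type_one_error_calibrated(self):
        """Random labels reject at ~ alpha (500 sims x 99 permutations)."""
        rng = np.random.default_rng(5)
        n = 24
        rejections = 0
        n_sim = 500
        for s in range(n_sim):
            X = rng.uniform(0, 1, size=(n, 10))
            D = bray_curtis(sites_frame(X))
            groups = pd.Series(rng.permutation(["a"] * 12 + ["b"] * 12))
            res = permanova(D, {"g": groups}, n_perm=99, seed=s)
            rejections += res.table.loc["g", "p_value"] <= 0.05
        rate = rejections / n_sim
        assert 0.025 <= rate <= 0.085

    def test_separated_clusters_maximal_r2_minimal_p(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 0.01, size=(8, 5)) + np.array([10, 0, 0, 0, 0.0])
        b = rng.uniform(0, 0.01, size=(8, 5)) + np.array([0, 10, 0, 0, 0.0])
        D = bray_curtis(sites_frame(np.vstack([a, b])))
        groups = _balanced_factors(2, 8)
        res = permanova(D, {"g": groups}, n_perm=999, seed=0)
        assert res.table.loc["g", "r2"] > 0.95
        assert res.table.loc["g", "p_value"] == pytest.approx(1.0 / 1000.0)

    def test_minimum_p_at_resolution(self):
        # with n_perm permutations the smallest attainable p is 1/(n_perm+1)
        rng = np.random.default_rng(7)
        X = np.vstack([np.eye(4) * 10 + rng.uniform(size=(4, 4)),
                       np.ones((4, 4)) + rng.uniform(size=(4, 4))])
        D = bray_curtis(sites_frame(X))
        res = permanova(D, {"g": _balanced_factors(2, 4)}, n_perm=199, seed=1)
        assert res.table.loc["g", "p_value"] >= 1.0 / 200.0

    def test_r2_sums_to_one(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0.1, 1, size=(18, 6))
        D = bray_curtis(sites_frame(X))
        t1 = _balanced_factors(3, 6)
        t2 = pd.Series(list(rng.choice(["u", "v"], size=18)))
        res = permanova(D, {"t1": t1, "t2": t2}, n_perm=49, seed=2)
        assert res.table["r2"].drop("Total").sum() == pytest.approx(1.0)

    def test_matches_one_way_oracle(self):
        """Observed pseudo-F and R2 agree with scikit-bio's PERMANOVA."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skb_permanova, DistanceMatrix

        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, size=(15, 8)) \
            + np.repeat(np.array([[0.5], [0.0], [1.0]]), 5, axis=0)
        D = bray_curtis(sites_frame(X))
        groups = _balanced_factors(3, 5)
        mine = permanova(D, {"g": groups}, n_perm=99, seed=3)
        theirs = skb_permanova(DistanceMatrix(D.to_numpy(), ids=list(D.index)),
                               grouping=list(groups), permutations=99)
        assert mine.table.loc["g", "pseudo_f"] == pytest.approx(
            theirs["test statistic"], rel=1e-6)

    def test_constant_term_rejected(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0.1, 1, size=(6, 4))
        D = bray_curtis(sites_frame(X))
        with pytest.raises(ValueError, match="constant"):
            permanova(D, {"g": pd.Series(["a"] * 6)}, n_perm=9, seed=0)


class TestInferenceTree:
    def test_specificity_under_independence(self):
        """No split in >= 90% of null simulations at alpha = 0.05."""
        rng = np.random.default_rng(11)
        n_sim, splits = 200, 0
        for _ in range(n_sim):
            years = np.repeat(np.arange(1, 9), 6)
            scores = rng.normal(size=len(years))
            tree = inference_tree(scores, years, alpha=0.05, min_leaf=5)
            splits += not tree.root.is_leaf
        assert splits / n_sim <= 0.10

    def test_recovers_planted_partition(self):
        """Years 1-3 vs 4-12 separated by a wide mean shift."""
        rng = np.random.default_rng(12)
        years = np.repeat(np.arange(1, 13), 6)
        scores = np.where(years <= 3, -2.0, 2.0) + rng.normal(scale=0.1,
                                                              size=len(years))
        tree = inference_tree(scores, years, alpha=0.05, min_leaf=7)
        assert not tree.root.is_leaf
        assert tree.root.left.years == (1, 2, 3)
        assert tree.root.right.years == tuple(range(4, 13))

    def test_single_year_trivial_leaf(self):
        tree = inference_tree(np.array([0.1, 0.2, 0.3]),
                              np.array([2, 2, 2]), min_leaf=1)
        assert tree.root.is_leaf
        assert tree.root.p_value is None

    def test_leaves_partition_years(self):
        rng = np.random.default_rng(13)
        years = np.repeat(np.arange(1, 9), 8)
        scores = 0.5 * years + rng.normal(size=len(years))
        tree = inference_tree(scores, years, alpha=0.05, min_leaf=7)
        got = sorted(y for g in tree.leaf_year_groups() for y in g)
        assert got == sorted(set(years))

    def test_min_leaf_larger_than_data_rejected(self):
        with pytest.raises(ValueError, match="min_leaf"):
            inference_tree(np.ones(3), np.array([1, 2, 3]), min_leaf=10)

    def test_unordered_mode_finds_noncontiguous_group(self):
        rng = np.random.default_rng(14)
        years = np.repeat(np.array([1, 2, 3, 4]), 10)
        scores = np.where(np.isin(years, [1, 3]), -2.0, 2.0) \
            + rng.normal(scale=0.1, size=len(years))
        tree = inference_tree(scores, years, alpha=0.05, min_leaf=5,
                              ordered=False)
        assert not tree.root.is_leaf
        groups = {tree.root.left.years, tree.root.right.years}
        assert (1, 3) in groups and (2, 4) in groups
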