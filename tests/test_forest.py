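import numpy as np
import pytest

from momirf.forest import (
    ForestParams,
    build_forest,
    find_best_split,
    grow_tree,
    identify_msrv,
    split_statistic,
    standardize_node_responses,
)


def brute_force_split(X, Ystar, nodesize=1):
    """Oracle: enumerate every (variable, cut) pair, minimizing the summed
    within-daughter sums of squares of the standardized responses."""
    n, p = X.shape
    best = None
    for v in range(p):
        for cut in np.unique(X[:, v])[:-1]:
            left = X[:, v] <= cut
            nL, nR = left.sum(), (~left).sum()
            if nL < nodesize or nR < nodesize:
                continue
            sse = 0.0
            for j in range(Ystar.shape[1]):
                yL, yR = Ystar[left, j], Ystar[~left, j]
                sse += ((yL - yL.mean()) ** 2).sum() + ((yR - yR.mean()) ** 2).sum()
            if best is None or sse < best[0] - 1e-12:
                best = (sse, v, cut)
    return best


class TestStandardization:
    def test_hand_example(self):
        z, inert = standardize_node_responses(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.ravel(), [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
        assert not inert[0]

    def test_constant_column_inert(self):
        z, inert = standardize_node_responses(np.array([[5.0], [5.0], [5.0]]))
        assert inert[0] and np.all(z == 0)

    def test_moment_contract(self, rng):
        Y = rng.normal(size=(17, 4)) * 10 + 3
        z, inert = standardize_node_responses(Y)
        assert not inert.any()
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose((z**2).mean(axis=0), 1, atol=1e-12)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            standardize_node_responses(np.empty((0, 2)))


class TestSplitStatistic:
    def test_separating_split(self):
        assert split_statistic(np.array([-1.0, -1, 1, 1]), [0, 1], [2, 3]) == pytest.approx(4.0)

    def test_balanced_split_zero(self):
        assert split_statistic(np.array([-1.0, 1, -1, 1]), [0, 1], [2, 3]) == pytest.approx(0.0)

    def test_inert_column_zero(self):
        assert split_statistic(np.zeros(6), [0, 1, 2], [3, 4, 5]) == 0.0

    def test_invalid_daughters(self):
        with pytest.raises(ValueError):
            split_statistic(np.ones(4), [], [0, 1, 2, 3])
        with pytest.raises(ValueError):
            split_statistic(np.ones(4), [0, 1], [1, 2, 3])


class TestFindBestSplit:
    def test_simple_cut(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        Ystar = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        var, cut, G, gq = find_best_split(X, Ystar, [0], nodesize=1)
        assert var == 0 and cut == pytest.approx(2.5) and gq == pytest.approx(4.0)

    def test_constant_predictors_give_none(self):
        X = np.ones((6, 3))
        Ystar, _ = standardize_node_responses(np.arange(6.0))
        assert find_best_split(X, Ystar, [0, 1, 2], nodesize=1) is None

    def test_matches_brute_force_oracle(self, rng):
        # exhaustive agreement between the fast kernel and direct enumeration
        for _ in range(40):
            n = int(rng.integers(4, 13))
            p = int(rng.integers(1, 5))
            q = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p)).round(1)  # ties likely
            Y = rng.normal(size=(n, q))
            Ystar, _ = standardize_node_responses(Y)
            res = find_best_split(X, Ystar, list(range(p)), nodesize=1)
            oracle = brute_force_split(X, Ystar, nodesize=1)
            if oracle is None:
                assert res is None
                continue
            var, cut, G, gq = res
            # equivalence of max-Gq and min-SSE criteria: same achieved score
            left = X[:, var] <= cut
            sse = 0.0
            for j in range(q):
                yL, yR = Ystar[left, j], Ystar[~left, j]
                sse += ((yL - yL.mean()) ** 2).sum() + ((yR - yR.mean()) ** 2).sum()
            assert sse == pytest.approx(oracle[0], abs=1e-9)
            assert gq == pytest.approx(G.sum(), abs=1e-9)

    def test_gq_equals_sum_of_split_statistics(self, rng):
        X = rng.normal(size=(10, 2))
        Ystar, _ = standardize_node_responses(rng.normal(size=(10, 3)))
        var, cut, G, gq = find_best_split(X, Ystar, [0, 1], nodesize=1)
        left = np.flatnonzero(X[:, var] <= cut)
        right = np.flatnonzero(X[:, var] > cut)
        manual = [split_statistic(Ystar[:, j], left, right) for j in range(3)]
        np.testing.assert_allclose(G, manual, atol=1e-9)


class TestIdentifyMsrv:
    @pytest.mark.parametrize("G, expected", [([0.1, 0.9, 0.3], 1), ([0.5, 0.5], 0), ([2.0], 0)])
    def test_argmax_with_ties(self, G, expected):
        assert identify_msrv(np.array(G)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            identify_msrv(np.array([]))


class TestGrowTree:
    def test_deterministic(self, small_latent):
        X = small_latent.datasets["omic1"].values
        Y = small_latent.datasets["omic2"].values
        p = ForestParams(ntree=1, seed=0)
        t1, t2 = grow_tree(X, Y, p, 5), grow_tree(X, Y, p, 5)
        np.testing.assert_array_equal(t1.feature, t2.feature)
        np.testing.assert_array_equal(t1.threshold, t2.threshold)
        np.testing.assert_array_equal(t1.inbag_count, t2.inbag_count)

    def test_single_response_is_always_msrv(self, rng):
        X = rng.normal(size=(40, 5))
        Y = X[:, :1] + 0.1 * rng.normal(size=(40, 1))
        tree = grow_tree(X, Y, ForestParams(ntree=1, seed=0), 3)
        internal = tree.feature >= 0
        assert internal.any()
        assert np.all(tree.msrv[internal] == 0)

    def test_node_bookkeeping(self, small_forest):
        # children partition the parent and sit one level deeper
        for tree in small_forest.trees_:
            for i in range(tree.n_nodes):
                if tree.feature[i] >= 0:
                    l, r = tree.left[i], tree.right[i]
                    assert tree.depth[l] == tree.depth[r] == tree.depth[i] + 1
                    assert tree.n_node[l] + tree.n_node[r] == tree.n_node[i]
                    assert tree.msrv[i] >= 0
                else:
                    assert tree.msrv[i] == -1 and tree.left[i] == -1

    def test_tiny_sample_gives_single_root(self, rng):
        X, Y = rng.normal(size=(4, 3)), rng.normal(size=(4, 2))
        tree = grow_tree(X, Y, ForestParams(ntree=1, nodesize=5, seed=0), 1)
        assert tree.n_nodes == 1 and tree.feature[0] == -1


class TestBuildForest:
    def test_tree_count_and_bootstrap_partition(self, small_forest):
        assert len(small_forest.trees_) == 30
        n = small_forest.n_samples_
        for tree in small_forest.trees_:
            assert tree.inbag_count.sum() == n
            inbag = set(tree.inbag_ids.tolist())
            oob = set(tree.oob_ids.tolist())
            assert inbag | oob == set(range(n)) and not inbag & oob

    def test_forest_determinism(self, small_latent):
        X = small_latent.datasets["omic1"].values
        Y = small_latent.datasets["omic2"].values
        p = ForestParams(ntree=5, seed=11)
        f1, f2 = build_forest(X, Y, p), build_forest(X, Y, p)
        for t1, t2 in zip(f1.trees_, f2.trees_):
            np.testing.assert_array_equal(t1.feature, t2.feature)
            np.testing.assert_array_equal(t1.msrv, t2.msrv)

    def test_every_tree_splits_on_informative_data(self, small_forest):
        assert all(t.max_node_depth >= 1 for t in small_forest.trees_)

    def test_sample_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="sample"):
            build_forest(rng.normal(size=(10, 3)), rng.normal(size=(11, 2)), ForestParams(ntree=1))

    def test_resp_frac_subsetting_runs(self, small_latent):
        X = small_latent.datasets["omic1"].values
        Y = small_latent.datasets["omic2"].values
        f = build_forest(X, Y, ForestParams(ntree=3, resp_frac=0.2, seed=1))
        for tree in f.trees_:
            internal = tree.feature >= 0
            assert np.all(tree.msrv[internal] < Y.shape[1])

    def test_nsplit_random_cuts_deterministic(self, small_latent):
        X = small_latent.datasets["omic1"].values
        Y = small_latent.datasets["omic2"].values
        p = ForestParams(ntree=3, nsplit=5, seed=2)
        f1, f2 = build_forest(X, Y, p), build_forest(X, Y, p)
        for t1, t2 in zip(f1.trees_, f2.trees_):
            np.testing.assert_array_equal(t1.threshold, t2.threshold)
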