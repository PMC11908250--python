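"""Multivariate regression trees and forests with per-split MSRV labels.

A multivariate random forest (MRF) is grown on a predictor matrix ``X``
(n x p) and a response matrix ``Y`` (n x q).  Every node split maximizes the
summed per-response statistic ``Gq*(s, t) = sum_j G_j`` over the within-node
standardized responses, and the response attaining the largest ``G_j`` at a
split is recorded as that node's *maximal splitting response variable*
(MSRV).  MSRV labels are what later give response variables a minimal depth,
so both sides of a two-omics pair can be ranked by one fitted forest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._split import (
    best_split_kernel,
    seed_kernel_rng,
    split_g_vector,
    standardize_node,
)

__all__ = [
    "ForestParams",
    "Tree",
    "MultivariateRandomForest",
    "standardize_node_responses",
    "split_statistic",
    "find_best_split",
    "identify_msrv",
    "grow_tree",
    "build_forest",
]


@dataclass(frozen=True)
class ForestParams:
    """Forest hyper-parameters.

    ``mtry`` defaults to ceil(p/3) (the regression convention), ``nodesize``
    to 5 and the split search to ``nsplit=10`` random cut points per candidate
    (the convention of regression forests in this field; ``nsplit=0`` requests
    an exhaustive search); ``resp_frac`` is
    the proportion of response variables scored at each node split (redrawn
    per split).
    """

    ntree: int = 100
    mtry: int | None = None
    resp_frac: float = 1.0
    nodesize: int = 5
    max_depth: int | None = None
    nsplit: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not (0.0 < self.resp_frac <= 1.0):
            raise ValueError("resp_frac must be in (0, 1]")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


class Tree:
    """One grown multivariate tree, stored as flat parallel arrays.

    ``feature[i] == -1`` marks a terminal node (then ``msrv[i] == -1`` too);
    internal nodes carry the split predictor, cut value, MSRV response index
    and the split score.  ``inbag_count`` holds the bootstrap multiplicity of
    every training sample; its zeros are the out-of-bag samples.
    """

    __slots__ = (
        "feature",
        "threshold",
        "msrv",
        "gq",
        "depth",
        "left",
        "right",
        "n_node",
        "inbag_count",
        "seed",
    )

    def __init__(self, feature, threshold, msrv, gq, depth, left, right, n_node, inbag_count, seed):
        self.feature = np.asarray(feature, dtype=np.int32)
        self.threshold = np.asarray(threshold, dtype=float)
        self.msrv = np.asarray(msrv, dtype=np.int32)
        self.gq = np.asarray(gq, dtype=float)
        self.depth = np.asarray(depth, dtype=np.int32)
        self.left = np.asarray(left, dtype=np.int32)
        self.right = np.asarray(right, dtype=np.int32)
        self.n_node = np.asarray(n_node, dtype=np.int32)
        self.inbag_count = np.asarray(inbag_count, dtype=np.int32)
        self.seed = int(seed)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def oob_ids(self) -> np.ndarray:
        return np.flatnonzero(self.inbag_count == 0)

    @property
    def inbag_ids(self) -> np.ndarray:
        return np.flatnonzero(self.inbag_count > 0)

    @property
    def max_node_depth(self) -> int:
        return int(self.depth.max())

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Terminal node index for every row of X."""
        X = np.asarray(X, dtype=float)
        cur = np.zeros(len(X), dtype=np.int64)
        while True:
            f = self.feature[cur]
            active = f >= 0
            if not active.any():
                return cur
            idx = np.flatnonzero(active)
            xv = X[idx, f[idx]]
            go_left = xv <= self.threshold[cur[idx]]
            cur[idx] = np.where(go_left, self.left[cur[idx]], self.right[cur[idx]])


def standardize_node_responses(Y_node: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize node responses to mean 0 and mean square 1.

    Returns ``(Y*, inert)`` where ``Y*[:, j] = sqrt(m) (y - ybar)/||y - ybar||``
    and ``inert[j]`` flags zero-variance columns (mapped to all-zeros).
    """
    Y_node = np.asarray(Y_node, dtype=float)
    if Y_node.ndim == 1:
        Y_node = Y_node[:, None]
    if Y_node.shape[0] == 0:
        raise ValueError("empty node")
    return standardize_node(np.ascontiguousarray(Y_node))


def split_statistic(ystar: np.ndarray, left_ids: Sequence[int], right_ids: Sequence[int]) -> float:
    """G_j = (sum_L y*)^2/n_L + (sum_R y*)^2/n_R for one standardized column."""
    ystar = np.asarray(ystar, dtype=float)
    left_ids = np.asarray(left_ids, dtype=int)
    right_ids = np.asarray(right_ids, dtype=int)
    if len(left_ids) == 0 or len(right_ids) == 0:
        raise ValueError("both daughters must be non-empty")
    if np.intersect1d(left_ids, right_ids).size:
        raise ValueError("daughters must be disjoint")
    if len(left_ids) + len(right_ids) != len(ystar):
        raise ValueError("daughters must cover the node")
    sL = ystar[left_ids].sum()
    sR = ystar[right_ids].sum()
    return float(sL**2 / len(left_ids) + sR**2 / len(right_ids))


def identify_msrv(G: np.ndarray) -> int:
    """Index of the maximal per-response split statistic (ties -> smallest)."""
    G = np.asarray(G, dtype=float)
    if G.size == 0:
        raise ValueError("empty split-statistic vector")
    return int(np.argmax(G))


def find_best_split(
    X_node: np.ndarray,
    Ystar_node: np.ndarray,
    candidate_vars: Sequence[int],
    nodesize: int = 5,
    nsplit: int = 0,
):
    """Best (variable, cut) over candidates and admissible midpoint cuts.

    Returns ``(split_var, split_value, G_vector, gq_star)`` or ``None`` when
    no admissible split exists.  ``split_var`` is an index into the original
    predictor columns; ``G_vector`` holds per-response statistics at the
    chosen split, whose argmax is the MSRV.
    """
    X_node = np.asarray(X_node, dtype=float)
    Ystar_node = np.ascontiguousarray(np.asarray(Ystar_node, dtype=float))
    candidate_vars = np.sort(np.asarray(candidate_vars, dtype=np.int64))
    Xc = np.ascontiguousarray(X_node[:, candidate_vars])
    c, cut, score = best_split_kernel(Xc, Ystar_node, nodesize, nsplit)
    if c < 0:
        return None
    var = int(candidate_vars[c])
    G = split_g_vector(np.ascontiguousarray(X_node[:, var]), Ystar_node, cut)
    return var, float(cut), G, float(score)


def _tree_seeds(seed: int, ntree: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(ntree)


def grow_tree(X: np.ndarray, Y: np.ndarray, params: ForestParams, tree_seed) -> Tree:
    """Grow one multivariate tree on a bootstrap sample.

    ``tree_seed`` may be an int or a ``SeedSequence``; bootstrap draws,
    per-split predictor candidates and response subsets all come from it.
    """
    X = np.ascontiguousarray(X, dtype=float)
    Y = np.ascontiguousarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must share the sample dimension")
    rng = np.random.default_rng(tree_seed)
    if params.nsplit > 0:
        seed_kernel_rng(int(rng.integers(0, 2**31 - 1)))
    mtry = params.mtry if params.mtry is not None else math.ceil(p / 3)
    mtry = min(mtry, p)
    q_sub = max(1, math.ceil(params.resp_frac * q))

    boot = rng.integers(0, n, size=n)
    inbag_count = np.bincount(boot, minlength=n)

    feature, threshold, msrv, gq, depth_arr, left, right, n_node = ([] for _ in range(8))

    def new_node(d, m):
        feature.append(-1)
        threshold.append(np.nan)
        msrv.append(-1)
        gq.append(np.nan)
        depth_arr.append(d)
        left.append(-1)
        right.append(-1)
        n_node.append(m)
        return len(feature) - 1

    root_idx = np.asarray(boot, dtype=np.int64)
    stack = [(new_node(0, len(root_idx)), root_idx, 0)]
    while stack:
        node_id, idx, d = stack.pop()
        m = len(idx)
        if m < 2 * params.nodesize:
            continue
        if params.max_depth is not None and d >= params.max_depth:
            continue
        if params.resp_frac < 1.0:
            sub = np.sort(rng.choice(q, size=q_sub, replace=False))
        else:
            sub = np.arange(q)
        Z, _ = standardize_node(np.ascontiguousarray(Y[idx][:, sub]))
        cand = np.sort(rng.choice(p, size=mtry, replace=False))
        Xn = X[idx]
        res = find_best_split(Xn, Z, cand, nodesize=params.nodesize, nsplit=params.nsplit)
        if res is None:
            continue
        var, cut, G, score = res
        j = identify_msrv(G)
        go_left = Xn[:, var] <= cut
        left_idx, right_idx = idx[go_left], idx[~go_left]
        feature[node_id] = var
        threshold[node_id] = cut
        msrv[node_id] = int(sub[j])
        gq[node_id] = score
        lid = new_node(d + 1, len(left_idx))
        rid = new_node(d + 1, len(right_idx))
        left[node_id], right[node_id] = lid, rid
        # push right first so the left child is processed first (cosmetic;
        # results are order-independent)
        stack.append((rid, right_idx, d + 1))
        stack.append((lid, left_idx, d + 1))
    return Tree(
        feature, threshold, msrv, gq, depth_arr, left, right, n_node, inbag_count,
        seed=0 if not np.isscalar(tree_seed) else int(tree_seed),
    )


class MultivariateRandomForest(BaseEstimator):
    """Multivariate random forest with MSRV bookkeeping.

    Parameters mirror :class:`ForestParams`; ``random_state`` seeds the
    deterministic per-tree seed derivation, so two fits with identical
    parameters produce identical forests regardless of execution order.

    Attributes (after :meth:`fit`)
    ------------------------------
    trees_ : list of :class:`Tree`
    n_features_in_, n_responses_ : int
    feature_ids_, response_ids_ : column identifiers (from DataFrames when
        given, else ``X1..Xp`` / ``Y1..Yq``).
    """

    def __init__(
        self,
        ntree: int = 100,
        mtry: int | None = None,
        resp_frac: float = 1.0,
        nodesize: int = 5,
        max_depth: int | None = None,
        nsplit: int = 10,
        random_state: int = 0,
    ):
        self.ntree = ntree
        self.mtry = mtry
        self.resp_frac = resp_frac
        self.nodesize = nodesize
        self.max_depth = max_depth
        self.nsplit = nsplit
        self.random_state = random_state

    def _params(self) -> ForestParams:
        return ForestParams(
            ntree=self.ntree,
            mtry=self.mtry,
            resp_frac=self.resp_frac,
            nodesize=self.nodesize,
            max_depth=self.max_depth,
            nsplit=self.nsplit,
            seed=self.random_state,
        )

    def fit(self, X, Y):
        feature_ids = list(X.columns) if hasattr(X, "columns") else []
        response_ids = list(Y.columns) if hasattr(Y, "columns") else []
        X = np.ascontiguousarray(np.asarray(X, dtype=float))
        Y = np.ascontiguousarray(np.asarray(Y, dtype=float))
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"sample mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}"
            )
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("missing values are not supported; filter them upstream")
        params = self._params()
        self.feature_ids_ = feature_ids or [f"X{j+1}" for j in range(X.shape[1])]
        self.response_ids_ = response_ids or [f"Y{j+1}" for j in range(Y.shape[1])]
        self.n_samples_ = X.shape[0]
        self.n_features_in_ = X.shape[1]
        self.n_responses_ = Y.shape[1]
        self.X_ = X
        self.Y_ = Y
        seeds = _tree_seeds(params.seed, params.ntree)
        self.trees_ = [grow_tree(X, Y, params, s) for s in seeds]
        return self

    def predict(self, X) -> np.ndarray:
        """Forest response prediction: average of per-tree terminal means."""
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        pred = np.zeros((len(X), self.n_responses_))
        for tree in self.trees_:
            leaf_train = tree.apply(self.X_)
            leaves = tree.apply(X)
            L = tree.n_nodes
            w = tree.inbag_count.astype(float)
            denom = np.bincount(leaf_train, weights=w, minlength=L)
            denom[denom == 0] = 1.0
            sums = np.zeros((L, self.n_responses_))
            np.add.at(sums, leaf_train, self.Y_ * w[:, None])
            pred += sums[leaves] / denom[leaves, None]
        return pred / len(self.trees_)

    # convenience accessors (thin wrappers over the imd/oob modules)
    def imd_profiles(self):
        from .imd import forest_imd

        check_is_fitted(self, "trees_")
        return forest_imd(self)

    def oob_report(self):
        from .oob import oob_report

        check_is_fitted(self, "trees_")
        return oob_report(self, self.X_, self.Y_)


def build_forest(X, Y, params: ForestParams) -> MultivariateRandomForest:
    """Functional entry point: grow a forest from a :class:`ForestParams`."""
    est = MultivariateRandomForest(
        ntree=params.ntree,
        mtry=params.mtry,
        resp_frac=params.resp_frac,
        nodesize=params.nodesize,
        max_depth=params.max_depth,
        nsplit=params.nsplit,
        random_state=params.seed,
    )
    return est.fit(X, Y)
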