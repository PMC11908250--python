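"""Out-of-bag (OOB) error for responses and predictors of a fitted forest.

Responses are scored by the usual bagged prediction: a sample's prediction in
each tree where it is out-of-bag is the bootstrap-weighted terminal-node mean
of the in-bag members, averaged over those trees.  Predictors have no direct
prediction path, so they are scored through *forest weights*: for an OOB
sample i, each tree contributes a probability distribution over its in-bag
samples proportional to their bootstrap multiplicity inside i's terminal
node; pooling those distributions over i's OOB trees and renormalizing gives
nonnegative weights w_ik summing to 1, and the predicted row is
``X_hat_i = sum_k w_ik X_k``.  Per-variable errors are mean squared
differences over samples covered by at least one OOB tree; the mean OOB
error averages all p + q per-variable errors and is the tuning criterion for
the tau-filter selection rule and for ranking direction models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forest import MultivariateRandomForest

__all__ = [
    "OobReport",
    "forest_oob_weights",
    "response_oob_predict",
    "response_oob_error",
    "predictor_oob_predict",
    "predictor_oob_error",
    "mean_oob_error",
    "oob_report",
]


@dataclass
class OobReport:
    per_response_err: np.ndarray
    per_predictor_err: np.ndarray
    mean_err: float


def response_oob_predict(forest: MultivariateRandomForest, X, Y) -> tuple[np.ndarray, np.ndarray]:
    """OOB response predictions and the per-sample covered mask."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, q = Y.shape
    pred = np.zeros((n, q))
    count = np.zeros(n)
    for tree in forest.trees_:
        leaves = tree.apply(X)
        w = tree.inbag_count.astype(float)
        L = tree.n_nodes
        denom = np.bincount(leaves, weights=w, minlength=L)
        sums = np.zeros((L, q))
        np.add.at(sums, leaves, Y * w[:, None])
        oob = w == 0
        leaf_oob = leaves[oob]
        ok = denom[leaf_oob] > 0
        rows = np.flatnonzero(oob)[ok]
        pred[rows] += sums[leaf_oob[ok]] / denom[leaf_oob[ok], None]
        count[rows] += 1
    covered = count > 0
    pred[covered] /= count[covered, None]
    return pred, covered


def response_oob_error(forest: MultivariateRandomForest, X, Y) -> np.ndarray:
    """Per-response mean squared OOB error over covered samples."""
    Y = np.asarray(Y, dtype=float)
    pred, covered = response_oob_predict(forest, X, Y)
    if not covered.any():
        raise ValueError("forest has zero OOB coverage; grow more trees")
    resid = Y[covered] - pred[covered]
    return (resid**2).mean(axis=0)


def forest_oob_weights(forest: MultivariateRandomForest, X) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized forest weights W (n x n) and the covered-sample mask.

    ``W[i, k]`` is the pooled terminal co-occupancy weight of in-bag sample k
    for OOB sample i; rows of covered samples sum to 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    W = np.zeros((n, n))
    count = np.zeros(n)
    for tree in forest.trees_:
        leaves = tree.apply(X)
        w = tree.inbag_count.astype(float)
        L = tree.n_nodes
        denom = np.bincount(leaves, weights=w, minlength=L)
        # per-leaf distribution over in-bag samples
        dist = np.zeros((L, n))
        dist[leaves, np.arange(n)] = w
        ok_leaf = denom > 0
        dist[ok_leaf] /= denom[ok_leaf, None]
        oob = w == 0
        rows = np.flatnonzero(oob)
        good = ok_leaf[leaves[rows]]
        rows = rows[good]
        W[rows] += dist[leaves[rows]]
        count[rows] += 1
    covered = count > 0
    W[covered] /= count[covered, None]
    return W, covered


def predictor_oob_predict(forest: MultivariateRandomForest, X) -> tuple[np.ndarray, np.ndarray]:
    """Forest-weight OOB prediction of the predictor matrix.

    Returns ``(X_hat, covered)``; rows of samples never OOB are zero and
    flagged out in ``covered``.
    """
    X = np.asarray(X, dtype=float)
    W, covered = forest_oob_weights(forest, X)
    return W @ X, covered


def predictor_oob_error(forest: MultivariateRandomForest, X) -> np.ndarray:
    """Per-predictor mean squared OOB error over covered samples."""
    X = np.asarray(X, dtype=float)
    pred, covered = predictor_oob_predict(forest, X)
    if not covered.any():
        raise ValueError("forest has zero OOB coverage; grow more trees")
    resid = X[covered] - pred[covered]
    return (resid**2).mean(axis=0)


def mean_oob_error(per_response_err, per_predictor_err) -> float:
    """Arithmetic mean of the concatenated p + q per-variable OOB errors."""
    both = np.concatenate([np.asarray(per_response_err, float).ravel(),
                           np.asarray(per_predictor_err, float).ravel()])
    return float(both.mean())


def oob_report(forest: MultivariateRandomForest, X, Y) -> OobReport:
    resp = response_oob_error(forest, X, Y)
    pred = predictor_oob_error(forest, X)
    return OobReport(resp, pred, mean_oob_error(resp, pred))
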