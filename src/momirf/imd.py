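"""Minimal depth and inverse minimal depth (IMD) over a fitted forest.

A variable's *minimal depth* in one tree is the shallowest depth at which it
appears — as the split variable for predictors, as the MSRV label for
responses.  Its *inverse minimal depth* is ``1/(depth + 1)``, or exactly 0
when the variable never appears in the tree, so IMD lives in [0, 1] with
larger values marking stronger variables.  The forest IMD is the per-variable
mean over all trees (zeros included), and the t-score IMD standardizes it by
the grand mean over variables of the same side and the variable's standard
error across trees.

The reference depth distributions of a weak variable under balanced-tree
assumptions are also provided (``weak_md_pmf`` and the general ``md_pmf``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forest import MultivariateRandomForest, Tree

__all__ = [
    "ImdProfile",
    "tree_minimal_depths",
    "inverse_minimal_depth",
    "forest_imd",
    "weak_md_pmf",
    "md_pmf",
    "imd_pmf",
]


@dataclass
class ImdProfile:
    """Per-variable IMD summary for one side (predictor or response) of a forest.

    per_tree_imd is an (ntree x nvars) matrix in [0, 1] whose entries are 0
    for variables not appearing in that tree; forest_imd is its column mean,
    se the per-variable standard error across trees, mu the grand mean of
    forest_imd, and tscore = (forest_imd - mu) / se.
    """

    side: str
    feature_ids: list
    per_tree_imd: np.ndarray
    forest_imd: np.ndarray
    se: np.ndarray
    tscore: np.ndarray
    mu: float

    def as_dict(self) -> dict:
        return {
            "side": self.side,
            "feature_ids": list(self.feature_ids),
            "forest_imd": self.forest_imd.tolist(),
            "se": self.se.tolist(),
            "tscore": self.tscore.tolist(),
            "mu": self.mu,
        }


def tree_minimal_depths(tree: Tree, side: str) -> dict[int, int]:
    """Map variable index -> minimal depth within one tree.

    ``side="predictor"`` scans split variables, ``side="response"`` MSRV
    labels.  Variables never appearing are absent from the map.
    """
    if side == "predictor":
        vars_ = tree.feature
    elif side == "response":
        vars_ = tree.msrv
    else:
        raise ValueError("side must be 'predictor' or 'response'")
    out: dict[int, int] = {}
    internal = vars_ >= 0
    for v, d in zip(vars_[internal].tolist(), tree.depth[internal].tolist()):
        if v not in out or d < out[v]:
            out[v] = d
    return out


def inverse_minimal_depth(depth: int | None) -> float:
    """IMD = 1/(depth + 1); 0 for a variable absent from the tree."""
    if depth is None:
        return 0.0
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    return 1.0 / (depth + 1.0)


def _tscore(forest_mean: np.ndarray, se: np.ndarray, mu: float) -> np.ndarray:
    """t-score with a +/-inf sentinel for zero-SE variables off the mean."""
    t = np.zeros_like(forest_mean)
    pos = se > 0
    t[pos] = (forest_mean[pos] - mu) / se[pos]
    degen = ~pos & (forest_mean != mu)
    t[degen] = np.sign(forest_mean[degen] - mu) * np.inf
    return t


def _side_profile(trees: Sequence[Tree], side: str, nvars: int, ids: list) -> ImdProfile:
    B = len(trees)
    per_tree = np.zeros((B, nvars))
    for b, tree in enumerate(trees):
        for v, d in tree_minimal_depths(tree, side).items():
            per_tree[b, v] = 1.0 / (d + 1.0)
    forest_mean = per_tree.mean(axis=0)
    se = per_tree.std(axis=0, ddof=1) / np.sqrt(B) if B > 1 else np.zeros(nvars)
    mu = float(forest_mean.mean())
    return ImdProfile(
        side=side,
        feature_ids=list(ids),
        per_tree_imd=per_tree,
        forest_imd=forest_mean,
        se=se,
        tscore=_tscore(forest_mean, se, mu),
        mu=mu,
    )


def forest_imd(forest: MultivariateRandomForest) -> tuple[ImdProfile, ImdProfile]:
    """(predictor profile, response profile) for a fitted forest.

    The two sides are standardized separately: each gets its own grand mean
    mu, and profiles are never pooled across sides.
    """
    pred = _side_profile(forest.trees_, "predictor", forest.n_features_in_, forest.feature_ids_)
    resp = _side_profile(forest.trees_, "response", forest.n_responses_, forest.response_ids_)
    return pred, resp


def weak_md_pmf(p: int, d: int) -> float:
    """P(D_v = d) for a weak variable in a balanced tree with p features.

    Equals ``(1 - 1/p)^(2^d - 1) * (1 - (1 - 1/p)^(2^d))``: the variable
    misses every one of the ``L_d = 2^d - 1`` shallower nodes and hits at
    least one of the ``2^d`` nodes at depth d.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if d < 0:
        raise ValueError("d must be >= 0")
    miss = 1.0 - 1.0 / p
    ell_d = 2.0**d
    return miss ** (ell_d - 1.0) * (1.0 - miss**ell_d)


def md_pmf(pi_theta: Sequence[float], ell: Sequence[int], d: int) -> float:
    """General minimal-depth pmf given per-depth split probabilities.

    ``pi_theta[j]`` is the probability the variable both enters the candidate
    set and wins the split of one node at depth j; ``ell[j]`` is the node
    count at depth j.  ``weak_md_pmf`` is the special case pi_theta = 1/p,
    ell = 2^j.
    """
    pi_theta = np.asarray(pi_theta, dtype=float)
    ell = np.asarray(ell, dtype=float)
    if np.any((pi_theta < 0) | (pi_theta > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any(ell <= 0):
        raise ValueError("node counts must be positive")
    if d < 0 or d >= len(pi_theta):
        raise ValueError("d out of range")
    survive = np.prod((1.0 - pi_theta[:d]) ** ell[:d])
    return float(survive * (1.0 - (1.0 - pi_theta[d]) ** ell[d]))


def imd_pmf(pi_theta: Sequence[float], ell: Sequence[int], d_inv: float) -> float:
    """pmf of the inverse minimal depth, via the change of variable d = 1/d_inv - 1."""
    if not (0.0 < d_inv <= 1.0):
        raise ValueError("d_inv must lie in (0, 1]")
    d = round(1.0 / d_inv - 1.0)
    return md_pmf(pi_theta, ell, d)
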