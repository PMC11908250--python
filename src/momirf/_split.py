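"""Numba kernels for the multivariate split search.

All per-node arithmetic happens here: within-node response standardization,
the summed per-response split statistic, and the exhaustive (or randomized)
search over candidate predictors and cut points.

The split statistic for response j at a cut partitioning a node of size m
into daughters of sizes nL / nR is

    G_j = (sum_L y*)^2 / nL + (sum_R y*)^2 / nR

over the within-node standardized response y* (mean 0, mean square 1).
Because the node-centered sums satisfy sum_R = -sum_L, this reduces to
``cum^2 * (1/nL + 1/nR)`` with ``cum`` the left prefix sum of y*, which is
what the kernels accumulate.  Maximizing the sum over responses is
algebraically equivalent to minimizing the summed within-daughter sums of
squares of the standardized responses.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["standardize_node", "best_split_kernel", "split_g_vector", "seed_kernel_rng"]


@njit(cache=True)
def seed_kernel_rng(seed):
    """Seed numba's internal RNG (used only for randomized cut sampling)."""
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def standardize_node(Ynode):
    """Within-node 0-1 standardization: y* = sqrt(m) (y - ybar) / ||y - ybar||.

    Columns with (near-)zero within-node variance are mapped to all-zeros;
    the returned mask flags them inert.
    """
    m, q = Ynode.shape
    Z = np.empty((m, q))
    inert = np.zeros(q, dtype=np.bool_)
    for j in range(q):
        mean = 0.0
        for i in range(m):
            mean += Ynode[i, j]
        mean /= m
        ss = 0.0
        for i in range(m):
            d = Ynode[i, j] - mean
            ss += d * d
        if ss <= 1e-24 * m:
            for i in range(m):
                Z[i, j] = 0.0
            inert[j] = True
        else:
            f = np.sqrt(m / ss)
            for i in range(m):
                Z[i, j] = (Ynode[i, j] - mean) * f
    return Z, inert


@njit(cache=True, fastmath=True)
def split_g_vector(x, Z, cut):
    """Per-response split statistics G_j for the split ``x <= cut``."""
    m, q = Z.shape
    nL = 0
    cum = np.zeros(q)
    for i in range(m):
        if x[i] <= cut:
            nL += 1
            for j in range(q):
                cum[j] += Z[i, j]
    nR = m - nL
    G = np.zeros(q)
    if nL == 0 or nR == 0:
        return G
    w = 1.0 / nL + 1.0 / nR
    for j in range(q):
        G[j] = cum[j] * cum[j] * w
    return G


@njit(cache=True, fastmath=True)
def best_split_kernel(Xc, Z, min_leaf, nsplit):
    """Search candidate columns of Xc for the cut maximizing sum_j G_j.

    Xc : (m, n_candidates) predictor values within the node, candidate
        columns ordered by ascending predictor index (ties break toward the
        smaller index / smaller cut).
    Z : (m, q) standardized responses.
    nsplit : if > 0, score at most ``nsplit`` randomly chosen admissible cut
        positions per candidate instead of all of them.

    Returns (best_candidate, best_cut, best_score); best_candidate is -1 when
    no admissible split exists.
    """
    m, pc = Xc.shape
    q = Z.shape[1]
    best_c = -1
    best_cut = 0.0
    best_score = -1.0
    cum = np.empty(q)
    use_pos = np.empty(m, dtype=np.bool_)
    for c in range(pc):
        x = Xc[:, c]
        order = np.argsort(x)
        # admissible positions: both daughters >= min_leaf, boundary values distinct
        nvalid = 0
        for k in range(1, m):
            ok = (
                k >= min_leaf
                and (m - k) >= min_leaf
                and x[order[k]] > x[order[k - 1]]
            )
            use_pos[k] = ok
            if ok:
                nvalid += 1
        if nvalid == 0:
            continue
        if nsplit > 0 and nvalid > nsplit:
            # reservoir-free subsampling: collect valid positions, partial
            # Fisher-Yates pick of nsplit of them
            valid = np.empty(nvalid, dtype=np.int64)
            t = 0
            for k in range(1, m):
                if use_pos[k]:
                    valid[t] = k
                    t += 1
                    use_pos[k] = False
            for t in range(nsplit):
                r = t + np.random.randint(0, nvalid - t)
                tmp = valid[t]
                valid[t] = valid[r]
                valid[r] = tmp
                use_pos[valid[t]] = True
        for j in range(q):
            cum[j] = 0.0
        for k in range(1, m):
            row = order[k - 1]
            for j in range(q):
                cum[j] += Z[row, j]
            if not use_pos[k]:
                continue
            s = 0.0
            for j in range(q):
                s += cum[j] * cum[j]
            score = s * (1.0 / k + 1.0 / (m - k))
            if score > best_score:
                best_score = score
                best_c = c
                best_cut = 0.5 * (x[order[k - 1]] + x[order[k]])
    return best_c, best_cut, best_score
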