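"""Synthetic multi-omics generators with known cross-correlated variables.

Two generative models are provided:

* a *latent model*: every dataset ``X^(m) = g_m(u) w_m^T + eps_m`` shares a
  single latent Gaussian vector ``u`` passed through a per-dataset kernel
  (square / exponential / identity), with only the first ``p_c[m]`` weight
  entries nonzero — those columns are the cross-correlated ("true") features;

* a *non-linear regression model*: grouped predictor copies of Gaussian basis
  variables with increasing noise, and responses formed from pairs of basis
  variables through exponential/logistic kernels.

All generated columns are standardized (mean 0, sd 1, ddof=1) and each
generator returns the boolean truth mask identifying cross-correlated columns,
so downstream selection stages can be benchmarked without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LatentScenario",
    "NonlinearScenario",
    "SimulatedData",
    "normalize_weights",
    "gen_latent",
    "gen_nonlinear",
]

_KERNELS = {
    "square": np.square,
    "exp": np.exp,
    "identity": lambda u: u,
}


@dataclass(frozen=True)
class LatentScenario:
    """Configuration of one latent-model simulation.

    Parameters
    ----------
    n : sample count shared by all datasets.
    p : features per dataset.
    p_c : cross-correlated feature count per dataset (first ``p_c[m]`` columns).
    sigma_u : standard deviation of the latent variable ``u`` (default 2).
    noise_sd : standard deviation of the independent Gaussian noise added to
        every entry (the diagonal of the noise covariance; default 0.3).
    kernels : per-dataset kernel tags from {"square", "exp", "identity"};
        defaults to that order truncated to the number of datasets.
    seed : RNG seed.
    """

    n: int
    p: Sequence[int]
    p_c: Sequence[int]
    sigma_u: float = 2.0
    noise_sd: float = 0.3
    kernels: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if not (2 <= len(self.p) <= 3):
            raise ValueError("latent model supports 2 or 3 datasets")
        if len(self.p_c) != len(self.p):
            raise ValueError("p and p_c must have equal length")
        for pm, pc in zip(self.p, self.p_c):
            if not (0 <= pc <= pm):
                raise ValueError(f"need 0 <= p_c <= p, got p_c={pc}, p={pm}")
        if self.sigma_u <= 0:
            raise ValueError("sigma_u must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        kernels = self.kernels
        if kernels is None:
            kernels = ("square", "exp", "identity")[: len(self.p)]
            object.__setattr__(self, "kernels", kernels)
        if len(self.kernels) != len(self.p):
            raise ValueError("one kernel tag per dataset required")
        for k in self.kernels:
            if k not in _KERNELS:
                raise ValueError(f"unknown kernel {k!r}; choose from {sorted(_KERNELS)}")


@dataclass(frozen=True)
class NonlinearScenario:
    """Configuration of one non-linear regression simulation.

    ``p2c`` cross-correlated responses are built from ``p_l = 2*p2c`` Gaussian
    basis variables; each basis variable spawns a group of ``g`` predictor
    copies with noise scale growing across the group.  ``pd1`` / ``pd2``
    independent standard-normal noise columns are appended to X / Y.
    """

    n: int
    p2c: int
    g: int = 1
    pd1: int = 0
    pd2: int = 0
    seed: int = 0
    basis_indexing: str = "pairs"  # "pairs" (u_{2k-1},u_{2k}) or "3k" (u_{3k-2},u_{3k-1})

    def __post_init__(self):
        if self.p2c < 1:
            raise ValueError("p2c must be >= 1")
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if self.pd1 < 0 or self.pd2 < 0:
            raise ValueError("noise counts must be nonnegative")
        if self.basis_indexing not in ("pairs", "3k"):
            raise ValueError("basis_indexing must be 'pairs' or '3k'")

    @property
    def p_l(self) -> int:
        """Number of basis variables forming Y."""
        return 2 * self.p2c

    @property
    def p1c(self) -> int:
        """Number of cross-correlated predictor columns (g * p_l)."""
        return self.g * self.p_l


@dataclass
class SimulatedData:
    """Generated datasets plus per-dataset truth masks.

    ``datasets`` maps a dataset tag to a samples x features DataFrame;
    ``truth`` maps the same tag to a boolean mask over its columns marking the
    cross-correlated variables.
    """

    datasets: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: dict[str, np.ndarray] = field(default_factory=dict)

    def tags(self) -> list[str]:
        return list(self.datasets)


def normalize_weights(w0: np.ndarray) -> np.ndarray:
    """Rescale a raw weight vector to unit energy (sum of squares = 1).

    Zero entries stay exactly zero.  Raises ``ValueError`` on an all-zero
    input, for which no unit-energy rescaling exists.
    """
    w0 = np.asarray(w0, dtype=float)
    norm = np.sqrt(np.sum(w0**2))
    if norm == 0.0:
        raise ValueError("cannot normalize an all-zero weight vector")
    return w0 / norm


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (M - mu) / sd


def _frame(M: np.ndarray, tag: str) -> pd.DataFrame:
    n, p = M.shape
    return pd.DataFrame(
        M,
        index=[f"s{i+1}" for i in range(n)],
        columns=[f"{tag}_v{j+1}" for j in range(p)],
    )


def gen_latent(scn: LatentScenario) -> SimulatedData:
    """Generate latent-model multi-omics data.

    A single latent vector ``u ~ N(0, sigma_u^2)`` of length ``n`` is shared
    by all datasets; dataset ``m`` is ``g_m(u) w_m^T + eps`` where only the
    first ``p_c[m]`` entries of ``w_m`` are nonzero (drawn U(-1,1) and
    normalized to unit sum of squares) and ``eps`` is i.i.d. Gaussian noise
    with sd ``noise_sd``.  Columns are standardized afterwards.
    """
    rng = np.random.default_rng(scn.seed)
    u = rng.normal(0.0, scn.sigma_u, size=scn.n)
    out = SimulatedData()
    for m, (pm, pc, kern) in enumerate(zip(scn.p, scn.p_c, scn.kernels)):
        tag = f"omic{m+1}"
        signal = np.zeros((scn.n, pm))
        if pc > 0:
            w = np.zeros(pm)
            w[:pc] = rng.uniform(-1.0, 1.0, size=pc)
            if not np.any(w):  # astronomically unlikely, but keep the contract
                w[:pc] = 1.0
            w = normalize_weights(w)
            signal = np.outer(_KERNELS[kern](u), w)
        eps = rng.normal(0.0, scn.noise_sd, size=(scn.n, pm)) if scn.noise_sd > 0 else 0.0
        M = _standardize_columns(signal + eps)
        mask = np.zeros(pm, dtype=bool)
        mask[:pc] = True
        out.datasets[tag] = _frame(M, tag)
        out.truth[tag] = mask
    return out


def gen_nonlinear(scn: NonlinearScenario) -> SimulatedData:
    """Generate non-linear regression model data.

    X columns: for each of the ``p_l`` basis variables ``U_i``, ``g`` copies
    ``U_i + (0.01 + 0.5 (j-1)/(g-1)) * eps`` (plain ``U_i + eps`` for g=1),
    followed by ``pd1`` pure-noise columns.  Y columns: ``p2c`` responses
    ``0.25 exp(4 u_a) + 4 / (1 + exp(-20 u_b)) - 0.5`` over basis pairs,
    followed by ``pd2`` pure-noise columns.
    """
    rng = np.random.default_rng(scn.seed)
    n, g, p_l = scn.n, scn.g, scn.p_l
    U = rng.normal(size=(n, p_l))

    xcols = []
    for i in range(p_l):
        for j in range(1, g + 1):
            scale = 1.0 if g == 1 else 0.01 + 0.5 * (j - 1) / (g - 1)
            xcols.append(U[:, i] + scale * rng.normal(size=n))
    X = np.column_stack(xcols)
    if scn.pd1 > 0:
        X = np.hstack([X, rng.normal(size=(n, scn.pd1))])

    ycols = []
    for k in range(1, scn.p2c + 1):
        if scn.basis_indexing == "pairs":
            a, b = 2 * k - 2, 2 * k - 1
        else:  # "3k": u_{3k-2}, u_{3k-1} taken modulo the available basis
            a, b = (3 * k - 3) % p_l, (3 * k - 2) % p_l
        ycols.append(0.25 * np.exp(4.0 * U[:, a]) + 4.0 / (1.0 + np.exp(-20.0 * U[:, b])) - 0.5)
    Y = np.column_stack(ycols)
    if scn.pd2 > 0:
        Y = np.hstack([Y, rng.normal(size=(n, scn.pd2))])

    out = SimulatedData()
    for tag, M, n_true in (("omic1", X, scn.p1c), ("omic2", Y, scn.p2c)):
        mask = np.zeros(M.shape[1], dtype=bool)
        mask[:n_true] = True
        out.datasets[tag] = _frame(_standardize_columns(M), tag)
        out.truth[tag] = mask
    return out
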