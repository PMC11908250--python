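"""The three IMD-based variable-selection rules.

* **filter** — keep variables whose forest IMD exceeds ``tau * sigma`` where
  sigma is the standard deviation of forest IMD across variables of that
  side; ``tau`` is tuned on a 0.1-step grid by refitting the forest on the
  kept variables and tracking the mean OOB error (response + predictor
  errors), choosing tau at the knee of the error curve — the point where
  further pruning stops buying real error reduction (see
  :func:`choose_tau_knee` for why the curve's minimum cannot be used).

* **mixture** — fit the zero-inflated two-component mixture to the forest
  IMD of one side and keep nonzero-IMD variables whose posterior probability
  of the low-mean (noise) component falls below ``pr``.

* **transformation** — threshold the t-score IMD at the magnitude of the
  Student-t 0.05-level quantile with ``ntree - 1`` degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .forest import ForestParams, MultivariateRandomForest, build_forest
from .imd import ImdProfile, forest_imd
from .mixture import ZeroInflatedGaussianMixture
from .oob import oob_report

__all__ = [
    "SelectionResult",
    "filter_support",
    "choose_tau_knee",
    "select_filter",
    "fit_mixture",
    "posterior_probs",
    "select_mixture",
    "select_transformation",
    "ImdFilterSelector",
    "ImdMixtureSelector",
    "ImdTScoreSelector",
]

DEFAULT_TAU_GRID = np.round(np.arange(0.1, 3.0 + 1e-9, 0.1), 10)


@dataclass
class SelectionResult:
    """Selected variables of one side plus the rule's diagnostics."""

    method: str
    side: str
    selected_ids: list
    selected_mask: np.ndarray
    threshold: float
    diagnostics: dict = field(default_factory=dict)


def filter_support(profile: ImdProfile, tau: float) -> np.ndarray:
    """Mask of variables with forest IMD > tau * sd(forest IMD of the side)."""
    sigma = float(np.std(profile.forest_imd, ddof=1))
    return profile.forest_imd > tau * sigma


def choose_tau_knee(curve: np.ndarray) -> float:
    """Pick tau at the knee of the (tau, mean OOB error) tuning curve.

    The kept-set mean OOB error decreases as tau grows — stricter filtering
    retains ever more predictable variables — so neither the minimum nor a
    within-tolerance-of-minimum rule can stop the pruning.  The knee (the
    grid point with the largest vertical drop below the chord joining the
    first and last evaluated points) marks where removing variables stops
    buying real error reduction; beyond it the decline is the selection
    artifact.  Falls back to the error minimum when the curve has no knee.
    """
    curve = np.asarray(curve, float)
    if len(curve) < 3:
        return float(curve[np.argmin(curve[:, 1]), 0])
    t0, e0 = curve[0, 0], curve[0, 1]
    t1, e1 = curve[-1, 0], curve[-1, 1]
    chord = e0 + (curve[:, 0] - t0) * (e1 - e0) / max(t1 - t0, 1e-12)
    gap = chord - curve[:, 1]
    if gap.max() <= 0:
        return float(curve[np.argmin(curve[:, 1]), 0])
    return float(curve[np.argmax(gap), 0])


def _result(method: str, profile: ImdProfile, mask: np.ndarray, threshold: float, diag: dict) -> SelectionResult:
    ids = [fid for fid, keep in zip(profile.feature_ids, mask) if keep]
    return SelectionResult(method, profile.side, ids, np.asarray(mask, bool), float(threshold), diag)


def select_filter(
    X,
    Y,
    params: ForestParams | None = None,
    forest: MultivariateRandomForest | None = None,
    tau_grid=None,
    k_repeats: int = 5,
    tuning_ntree: int | None = None,
    refit_max_frac: float = 0.5,
) -> tuple[SelectionResult, SelectionResult]:
    """tau-sigma filtering with OOB tuning; returns (predictor, response) results.

    The base forest supplies the IMD profiles; for every tau on the grid the
    forest is refitted on the kept variables of both sides (k_repeats times,
    fresh derived seeds) and the mean OOB error recorded; tau is chosen at
    the knee of the curve (:func:`choose_tau_knee`).  Identical kept sets at
    neighbouring taus share their refits.  ``tuning_ntree`` lets the tuning
    refits use a smaller forest than the base fit; tau values keeping more
    than ``refit_max_frac`` of all variables reuse the base forest's error
    (that part of the curve is flat and its refits are the most expensive).
    """
    if k_repeats < 1:
        raise ValueError("k_repeats must be >= 1")
    params = params or ForestParams()
    if forest is None:
        forest = build_forest(X, Y, params)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    tau_grid = DEFAULT_TAU_GRID if tau_grid is None else np.asarray(tau_grid, float)
    prof_x, prof_y = forest_imd(forest)
    base_err = oob_report(forest, X, Y).mean_err
    n_all = X.shape[1] + Y.shape[1]

    cache: dict[tuple, tuple[float, float]] = {}
    curve = []  # (tau, mean_err, sd_err)
    for tau in tau_grid:
        keep_x = filter_support(prof_x, tau)
        keep_y = filter_support(prof_y, tau)
        if not keep_x.any() or not keep_y.any():
            warnings.warn(f"tau={tau:g} keeps an empty side; skipped", stacklevel=2)
            continue
        if (keep_x.sum() + keep_y.sum()) / n_all > refit_max_frac:
            curve.append((float(tau), base_err, 0.0))
            continue
        key = (keep_x.tobytes(), keep_y.tobytes())
        if key not in cache:
            errs = []
            for r in range(k_repeats):
                sub_seed = int(
                    np.random.SeedSequence([params.seed, len(cache), r]).generate_state(1)[0]
                    % (2**31 - 1)
                )
                sub = ForestParams(
                    ntree=tuning_ntree or params.ntree,
                    mtry=None if params.mtry is None else min(params.mtry, int(keep_x.sum())),
                    resp_frac=params.resp_frac,
                    nodesize=params.nodesize,
                    max_depth=params.max_depth,
                    nsplit=params.nsplit,
                    seed=sub_seed,
                )
                f = build_forest(X[:, keep_x], Y[:, keep_y], sub)
                errs.append(oob_report(f, X[:, keep_x], Y[:, keep_y]).mean_err)
            errs = np.asarray(errs)
            cache[key] = (float(errs.mean()), float(errs.std(ddof=1)) if k_repeats > 1 else 0.0)
        mean_err, sd_err = cache[key]
        curve.append((float(tau), mean_err, sd_err))

    if not curve:
        raise ValueError("no tau on the grid keeps a non-empty set on both sides")
    curve_arr = np.asarray(curve)
    tau_star = choose_tau_knee(curve_arr)

    diag = {"oob_curve": curve_arr, "tau": tau_star, "k_repeats": k_repeats}
    res_x = _result("filter", prof_x, filter_support(prof_x, tau_star), tau_star, diag)
    res_y = _result("filter", prof_y, filter_support(prof_y, tau_star), tau_star, diag)
    return res_x, res_y


def fit_mixture(imd_values, model_kind: str = "gaussian") -> ZeroInflatedGaussianMixture:
    """Fit the zero-inflated mixture (``gaussian`` or ``truncated_normal``)."""
    if model_kind not in ("gaussian", "truncated_normal"):
        raise ValueError("model_kind must be 'gaussian' or 'truncated_normal'")
    return ZeroInflatedGaussianMixture(truncated=model_kind == "truncated_normal").fit(imd_values)


def posterior_probs(fit: ZeroInflatedGaussianMixture, x) -> np.ndarray:
    """Posterior probabilities over {zero atom, noise, signal} components."""
    return fit.predict_proba(x)


def select_mixture(
    profile: ImdProfile, pr: float = 0.05, model_kind: str = "gaussian"
) -> SelectionResult:
    """Keep nonzero-IMD variables with noise-component posterior < pr."""
    fit = fit_mixture(profile.forest_imd, model_kind)
    post = fit.predict_proba(profile.forest_imd)
    if pr >= 1.0:  # boundary: every nonzero-IMD variable qualifies
        mask = profile.forest_imd > 0
    else:
        mask = (profile.forest_imd > 0) & (post[:, 1] < pr)
    diag = {
        "p0": fit.p0_,
        "weight": fit.weight_,
        "means": fit.means_.tolist(),
        "sigmas": fit.sigmas_.tolist(),
        "loglik": fit.loglik_,
        "model_kind": model_kind,
    }
    return _result("mixture", profile, mask, pr, diag)


def select_transformation(
    profile: ImdProfile, alpha: float = 0.05, ntree: int | None = None, tail: str = "upper"
) -> SelectionResult:
    """Threshold t-score IMD at the Student-t quantile with df = ntree - 1.

    ``tail="upper"`` (default) uses the magnitude of the alpha-level cut,
    Q = t_{1-alpha, df}; ``tail="lower"`` applies the literal lower-tail cut
    -Q, which keeps nearly everything and is provided for comparison only.
    """
    if ntree is None:
        ntree = profile.per_tree_imd.shape[0]
    if ntree < 2:
        raise ValueError("ntree must be >= 2 for the t threshold (df = ntree - 1)")
    q_hi = float(stats.t.ppf(1 - alpha, df=ntree - 1))
    thr = q_hi if tail == "upper" else -q_hi
    mask = profile.tscore > thr
    return _result("transformation", profile, mask, thr, {"alpha": alpha, "df": ntree - 1, "tail": tail})


class _BaseImdSelector(BaseEstimator):
    """Shared plumbing: fit a forest (or accept one) and store both supports."""

    def __init__(self, ntree=100, mtry=None, resp_frac=1.0, nodesize=5,
                 max_depth=None, nsplit=10, random_state=0):
        self.ntree = ntree
        self.mtry = mtry
        self.resp_frac = resp_frac
        self.nodesize = nodesize
        self.max_depth = max_depth
        self.nsplit = nsplit
        self.random_state = random_state

    def _forest_params(self) -> ForestParams:
        return ForestParams(
            ntree=self.ntree, mtry=self.mtry, resp_frac=self.resp_frac,
            nodesize=self.nodesize, max_depth=self.max_depth,
            nsplit=self.nsplit, seed=self.random_state,
        )

    def _ensure_forest(self, X, Y, forest):
        return forest if forest is not None else build_forest(X, Y, self._forest_params())

    def get_support(self, side: str = "predictor") -> np.ndarray:
        res = self.result_x_ if side == "predictor" else self.result_y_
        return res.selected_mask

    def transform(self, X):
        """Reduce a predictor matrix to the selected predictor columns."""
        return np.asarray(X)[:, self.get_support("predictor")]


class ImdFilterSelector(_BaseImdSelector):
    """sklearn-style wrapper around :func:`select_filter`."""

    def __init__(self, ntree=100, mtry=None, resp_frac=1.0, nodesize=5, max_depth=None,
                 nsplit=10, random_state=0, tau_grid=None, k_repeats=5,
                 tuning_ntree=None, refit_max_frac=0.5):
        super().__init__(ntree, mtry, resp_frac, nodesize, max_depth, nsplit, random_state)
        self.tau_grid = tau_grid
        self.k_repeats = k_repeats
        self.tuning_ntree = tuning_ntree
        self.refit_max_frac = refit_max_frac

    def fit(self, X, Y, forest: MultivariateRandomForest | None = None):
        forest = self._ensure_forest(X, Y, forest)
        self.forest_ = forest
        self.result_x_, self.result_y_ = select_filter(
            np.asarray(X, float), np.asarray(Y, float),
            params=self._forest_params(), forest=forest,
            tau_grid=self.tau_grid, k_repeats=self.k_repeats,
            tuning_ntree=self.tuning_ntree, refit_max_frac=self.refit_max_frac,
        )
        self.tau_ = self.result_x_.threshold
        return self


class ImdMixtureSelector(_BaseImdSelector):
    """sklearn-style wrapper around :func:`select_mixture` (both sides)."""

    def __init__(self, ntree=100, mtry=None, resp_frac=1.0, nodesize=5, max_depth=None,
                 nsplit=10, random_state=0, pr=0.05, model_kind="gaussian"):
        super().__init__(ntree, mtry, resp_frac, nodesize, max_depth, nsplit, random_state)
        self.pr = pr
        self.model_kind = model_kind

    def fit(self, X, Y, forest: MultivariateRandomForest | None = None):
        forest = self._ensure_forest(X, Y, forest)
        self.forest_ = forest
        prof_x, prof_y = forest_imd(forest)
        self.result_x_ = select_mixture(prof_x, self.pr, self.model_kind)
        self.result_y_ = select_mixture(prof_y, self.pr, self.model_kind)
        return self


class ImdTScoreSelector(_BaseImdSelector):
    """sklearn-style wrapper around :func:`select_transformation` (both sides)."""

    def __init__(self, ntree=100, mtry=None, resp_frac=1.0, nodesize=5, max_depth=None,
                 nsplit=10, random_state=0, alpha=0.05, tail="upper"):
        super().__init__(ntree, mtry, resp_frac, nodesize, max_depth, nsplit, random_state)
        self.alpha = alpha
        self.tail = tail

    def fit(self, X, Y, forest: MultivariateRandomForest | None = None):
        forest = self._ensure_forest(X, Y, forest)
        self.forest_ = forest
        prof_x, prof_y = forest_imd(forest)
        self.result_x_ = select_transformation(prof_x, self.alpha, forest.ntree, self.tail)
        self.result_y_ = select_transformation(prof_y, self.alpha, forest.ntree, self.tail)
        return self
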