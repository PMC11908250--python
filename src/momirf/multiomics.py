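"""K-dataset integration: direction ranking, IMD aggregation, selection.

With more than one omics matrix the role assignment (which dataset is the
response, which the predictor) matters.  Directions are ranked cheaply on
PCA-reduced copies of the datasets: for every ordered pair (i <- j) a forest
is fitted on the reduced matrices and scored by its mean OOB error, and for
each response dataset the best predictor is kept.  The kept directions are
then refitted on the full (non-reduced) features — PCA is only a screening
device; feature-level selection always works on full-feature forests.

Every dataset appears as the response of exactly one model in the resulting
collection M; for K = 2 the collection is simply both directions, fitted on
full features directly.

Aggregation over M: a variable's score is the mean of its forest IMD over
every model where its dataset appears (response or predictor side); the
filter and mixture rules are applied to that mean profile; the
transformation rule thresholds the pooled profile's t-scores (a per-model
majority vote is available as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .forest import ForestParams, MultivariateRandomForest, build_forest
from .imd import ImdProfile, forest_imd
from .oob import oob_report
from .selection import (
    SelectionResult,
    select_mixture,
    select_transformation,
)

__all__ = [
    "DirectionModel",
    "IntegrationResult",
    "pca_reduce",
    "choose_directions",
    "aggregate_and_select",
    "MultiOmicsSelector",
]


@dataclass
class DirectionModel:
    """One chosen response <- predictor connection and its fitted forest."""

    response_tag: str
    predictor_tag: str
    mean_oob: float
    forest: MultivariateRandomForest | None = None

    def __post_init__(self):
        if self.response_tag == self.predictor_tag:
            raise ValueError("response and predictor datasets must differ")


@dataclass
class IntegrationResult:
    models: list[DirectionModel]
    mean_imd: dict[str, pd.Series] = field(default_factory=dict)
    selections: dict[str, SelectionResult] = field(default_factory=dict)


def pca_reduce(M, var_threshold: float = 0.8) -> np.ndarray:
    """Scores of the leading PCs reaching ``var_threshold`` cumulative variance."""
    if not (0.0 < var_threshold <= 1.0):
        raise ValueError("var_threshold must be in (0, 1]")
    M = np.asarray(M, dtype=float)
    if np.allclose(M.std(axis=0), 0.0):
        raise ValueError("constant matrix has no principal components")
    pca = PCA(svd_solver="full").fit(M)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    k = min(k, len(cum))
    return pca.transform(M)[:, :k]


def _fit_direction(datasets, resp, pred, params, seed_tag):
    sub_seed = int(np.random.SeedSequence([params.seed, seed_tag]).generate_state(1)[0] % (2**31 - 1))
    p = ForestParams(
        ntree=params.ntree, mtry=params.mtry, resp_frac=params.resp_frac,
        nodesize=params.nodesize, max_depth=params.max_depth,
        nsplit=params.nsplit, seed=sub_seed,
    )
    return build_forest(datasets[pred], datasets[resp], p)


def choose_directions(
    datasets: dict[str, pd.DataFrame],
    params: ForestParams | None = None,
    var_threshold: float = 0.8,
) -> list[DirectionModel]:
    """Build the model collection M over the given datasets.

    Every dataset appears as response in exactly one returned model.  For
    K = 2 the only possible connections are the two directions, so both are
    fitted on full features directly.  For K >= 3 every ordered pair is
    first scored on PCA-reduced matrices by mean OOB error, and the winning
    predictor per response dataset is refitted on full features.
    """
    params = params or ForestParams()
    tags = list(datasets)
    if len(tags) < 2:
        raise ValueError("need at least two datasets")
    n_set = {len(d) for d in datasets.values()}
    if len(n_set) != 1:
        raise ValueError("datasets must share the same samples")

    if len(tags) == 2:
        models = []
        for ti, resp in enumerate(tags):
            pred = tags[1 - ti]
            forest = _fit_direction(datasets, resp, pred, params, seed_tag=ti)
            err = oob_report(forest, np.asarray(datasets[pred], float),
                             np.asarray(datasets[resp], float)).mean_err
            models.append(DirectionModel(resp, pred, err, forest))
        return models

    reduced = {t: pca_reduce(datasets[t], var_threshold) for t in tags}
    scores: dict[tuple[str, str], float] = {}
    for ti, resp in enumerate(tags):
        for tj, pred in enumerate(tags):
            if resp == pred:
                continue
            f = _fit_direction(reduced, resp, pred, params, seed_tag=ti * len(tags) + tj)
            scores[(resp, pred)] = oob_report(f, reduced[pred], reduced[resp]).mean_err

    models = []
    for ti, resp in enumerate(tags):
        best_pred = min((p for p in tags if p != resp), key=lambda p: scores[(resp, p)])
        forest = _fit_direction(datasets, resp, best_pred, params, seed_tag=len(tags) ** 2 + ti)
        models.append(DirectionModel(resp, best_pred, scores[(resp, best_pred)], forest))
    return models


def _model_profiles(models: list[DirectionModel]) -> dict[str, list[ImdProfile]]:
    """Per-dataset IMD profiles over every model appearance (both sides)."""
    out: dict[str, list[ImdProfile]] = {}
    for m in models:
        if m.forest is None:
            continue
        prof_x, prof_y = forest_imd(m.forest)
        out.setdefault(m.response_tag, []).append(prof_y)
        out.setdefault(m.predictor_tag, []).append(prof_x)
    return out


def _mean_profile(profiles: list[ImdProfile], tag: str) -> ImdProfile:
    """Pool several IMD profiles of the same dataset into one.

    The per-tree IMD matrices of every model appearance are stacked, so the
    aggregated profile is that of one pooled forest: the mean IMD equals the
    mean over all appearances, and the standard error (hence the t-score) is
    taken across the pooled trees.
    """
    ids = profiles[0].feature_ids
    per_tree = np.concatenate([p.per_tree_imd for p in profiles], axis=0)
    fmean = per_tree.mean(axis=0)
    nb = per_tree.shape[0]
    se = per_tree.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.zeros_like(fmean)
    mu = float(fmean.mean())
    t = np.zeros_like(fmean)
    pos = se > 0
    t[pos] = (fmean[pos] - mu) / se[pos]
    t[~pos & (fmean != mu)] = np.sign(fmean[~pos & (fmean != mu)] - mu) * np.inf
    return ImdProfile(side=tag, feature_ids=ids, per_tree_imd=per_tree,
                      forest_imd=fmean, se=se, tscore=t, mu=mu)


def aggregate_and_select(
    models: list[DirectionModel],
    method: str,
    datasets: dict[str, pd.DataFrame] | None = None,
    params: ForestParams | None = None,
    tau_grid=None,
    k_repeats: int = 5,
    pr: float = 0.05,
    model_kind: str = "gaussian",
    alpha: float = 0.05,
    trans_vote: bool = False,
    tuning_ntree: int | None = None,
    refit_max_frac: float = 0.5,
) -> IntegrationResult:
    """Apply one selection rule across the model collection M.

    filter / mixture: the rule runs on each dataset's pooled mean-IMD
    profile.  transformation: by default the t-threshold is applied to the
    pooled profile as well (t-scores over the union of trees of every model
    the dataset appears in); ``trans_vote=True`` instead selects per model
    and keeps variables chosen by a strict majority of the models containing
    them.  The filter's tau is tuned on the forests of M (refits restricted
    to the kept variables, mean OOB error averaged over models); it requires
    ``datasets`` for the refits.
    """
    if method not in ("filter", "mixture", "transformation"):
        raise ValueError("method must be 'filter', 'mixture' or 'transformation'")
    by_tag = _model_profiles(models)
    result = IntegrationResult(models=models)
    mean_profiles = {tag: _mean_profile(profs, tag) for tag, profs in by_tag.items()}
    for tag, prof in mean_profiles.items():
        result.mean_imd[tag] = pd.Series(prof.forest_imd, index=prof.feature_ids)

    if method == "mixture":
        for tag, prof in mean_profiles.items():
            result.selections[tag] = select_mixture(prof, pr=pr, model_kind=model_kind)
        return result

    if method == "transformation" and not trans_vote:
        for tag, prof in mean_profiles.items():
            result.selections[tag] = select_transformation(prof, alpha=alpha)
        return result

    if method == "transformation":
        votes: dict[str, dict] = {tag: {} for tag in by_tag}
        appearances: dict[str, dict] = {tag: {} for tag in by_tag}
        for m in models:
            if m.forest is None:
                continue
            prof_x, prof_y = forest_imd(m.forest)
            for tag, prof in ((m.response_tag, prof_y), (m.predictor_tag, prof_x)):
                sel = select_transformation(prof, alpha=alpha, ntree=m.forest.ntree)
                for fid, keep in zip(prof.feature_ids, sel.selected_mask):
                    votes[tag][fid] = votes[tag].get(fid, 0) + int(keep)
                    appearances[tag][fid] = appearances[tag].get(fid, 0) + 1
        for tag, prof in mean_profiles.items():
            mask = np.array(
                [votes[tag].get(fid, 0) > appearances[tag].get(fid, 1) / 2
                 for fid in prof.feature_ids]
            )
            result.selections[tag] = SelectionResult(
                "transformation", tag,
                [fid for fid, k in zip(prof.feature_ids, mask) if k],
                mask, float("nan"), {"alpha": alpha, "rule": "strict majority"},
            )
        return result

    # --- filter with tau tuning across the forests of M ------------------
    if datasets is None:
        raise ValueError("the filter rule needs the original datasets for OOB refits")
    params = params or ForestParams()
    from .selection import DEFAULT_TAU_GRID, choose_tau_knee, filter_support

    tau_grid = DEFAULT_TAU_GRID if tau_grid is None else np.asarray(tau_grid, float)
    distinct = [(m.forest, m.response_tag, m.predictor_tag)
                for m in models if m.forest is not None]
    base_err = float(np.mean([m.mean_oob for m in models]))
    n_all = sum(d.shape[1] for d in datasets.values())

    cache: dict[tuple, tuple[float, float]] = {}
    curve = []
    for tau in tau_grid:
        keeps = {tag: filter_support(prof, tau) for tag, prof in mean_profiles.items()}
        if any(not k.any() for k in keeps.values()):
            warnings.warn(f"tau={tau:g} keeps an empty dataset; skipped", stacklevel=2)
            continue
        if sum(int(k.sum()) for k in keeps.values()) / n_all > refit_max_frac:
            curve.append((float(tau), base_err, 0.0))
            continue
        key = tuple(keeps[tag].tobytes() for tag in sorted(keeps))
        if key not in cache:
            errs = []
            for r in range(k_repeats):
                model_errs = []
                for fi, (forest, resp_tag, pred_tag) in enumerate(distinct):
                    sub_seed = int(
                        np.random.SeedSequence([params.seed, len(cache), r, fi]).generate_state(1)[0]
                        % (2**31 - 1)
                    )
                    Xs = np.asarray(datasets[pred_tag], float)[:, keeps[pred_tag]]
                    Ys = np.asarray(datasets[resp_tag], float)[:, keeps[resp_tag]]
                    sub = ForestParams(
                        ntree=tuning_ntree or params.ntree,
                        mtry=None if params.mtry is None else min(params.mtry, Xs.shape[1]),
                        resp_frac=params.resp_frac, nodesize=params.nodesize,
                        max_depth=params.max_depth, nsplit=params.nsplit, seed=sub_seed,
                    )
                    f = build_forest(Xs, Ys, sub)
                    model_errs.append(oob_report(f, Xs, Ys).mean_err)
                errs.append(np.mean(model_errs))
            errs = np.asarray(errs)
            cache[key] = (float(errs.mean()), float(errs.std(ddof=1)) if k_repeats > 1 else 0.0)
        mean_err, sd_err = cache[key]
        curve.append((float(tau), mean_err, sd_err))

    if not curve:
        raise ValueError("no tau on the grid keeps a non-empty set for every dataset")
    curve_arr = np.asarray(curve)
    tau_star = choose_tau_knee(curve_arr)
    for tag, prof in mean_profiles.items():
        mask = filter_support(prof, tau_star)
        result.selections[tag] = SelectionResult(
            "filter", tag, [fid for fid, k in zip(prof.feature_ids, mask) if k],
            mask, tau_star, {"oob_curve": curve_arr, "k_repeats": k_repeats},
        )
    return result


class MultiOmicsSelector(BaseEstimator):
    """End-to-end multi-omics variable selection.

    ``fit`` takes a mapping of dataset tag -> samples x features DataFrame,
    chooses directions, and applies the requested rule; fitted attributes
    hold the model collection (``models_``), per-dataset mean IMD
    (``mean_imd_``) and per-dataset :class:`SelectionResult` objects
    (``selections_``).
    """

    def __init__(self, method="transformation", ntree=100, mtry=None, resp_frac=1.0,
                 nodesize=5, max_depth=None, nsplit=10, random_state=0,
                 var_threshold=0.8, tau_grid=None, k_repeats=5, pr=0.05,
                 model_kind="gaussian", alpha=0.05, tuning_ntree=None,
                 refit_max_frac=0.5):
        self.method = method
        self.ntree = ntree
        self.mtry = mtry
        self.resp_frac = resp_frac
        self.nodesize = nodesize
        self.max_depth = max_depth
        self.nsplit = nsplit
        self.random_state = random_state
        self.var_threshold = var_threshold
        self.tau_grid = tau_grid
        self.k_repeats = k_repeats
        self.pr = pr
        self.model_kind = model_kind
        self.alpha = alpha
        self.tuning_ntree = tuning_ntree
        self.refit_max_frac = refit_max_frac

    def fit(self, datasets: dict[str, pd.DataFrame]):
        params = ForestParams(
            ntree=self.ntree, mtry=self.mtry, resp_frac=self.resp_frac,
            nodesize=self.nodesize, max_depth=self.max_depth,
            nsplit=self.nsplit, seed=self.random_state,
        )
        self.models_ = choose_directions(datasets, params, self.var_threshold)
        res = aggregate_and_select(
            self.models_, self.method, datasets=datasets, params=params,
            tau_grid=self.tau_grid, k_repeats=self.k_repeats,
            pr=self.pr, model_kind=self.model_kind, alpha=self.alpha,
            tuning_ntree=self.tuning_ntree, refit_max_frac=self.refit_max_frac,
        )
        self.result_ = res
        self.mean_imd_ = res.mean_imd
        self.selections_ = res.selections
        return self
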