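"""Benchmark harness: selection metrics over repeated simulation runs.

For each replicate a synthetic two- or three-omics dataset is generated,
directions are chosen, forests fitted, and each requested selection rule
applied; recall, precision, PR-AUC and model size are scored against the
generator's truth masks.  Recall, precision and PR-AUC are averaged across
datasets within a replicate; model size is the total count of selected
variables over all datasets.  Report rows give the mean and standard
deviation over replicates.

PR-AUC is computed as average precision (the step-rule area, no
interpolation) over the ranking score each rule actually thresholds: mean
forest IMD for the filter and mixture rules, t-score IMD for the
transformation rule.  Tied scores are grouped at a common threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .forest import ForestParams
from .multiomics import _mean_profile, _model_profiles, aggregate_and_select, choose_directions
from .simulate import LatentScenario, NonlinearScenario, gen_latent, gen_nonlinear

__all__ = ["confusion_and_rates", "pr_auc", "run_scenario"]

METRICS = ("pr_auc", "precision", "recall", "model_size")


def confusion_and_rates(selected: np.ndarray, truth: np.ndarray) -> dict:
    """tp/fp/fn counts plus recall and precision for one boolean selection.

    An empty selection has undefined precision; it is reported as 0 with
    ``precision_defined`` False.
    """
    selected = np.asarray(selected, bool)
    truth = np.asarray(truth, bool)
    if selected.shape != truth.shape:
        raise ValueError("selection and truth masks must align")
    tp = int(np.sum(selected & truth))
    fp = int(np.sum(selected & ~truth))
    fn = int(np.sum(~selected & truth))
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    defined = (tp + fp) > 0
    precision = tp / (tp + fp) if defined else 0.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "recall": recall,
        "precision": precision,
        "precision_defined": defined,
    }


def pr_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Average-precision area under the precision-recall curve.

    All-equal scores carry no ranking information; the prevalence (the AP of
    a constant ranking) is returned with a warning.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    if truth.sum() == 0:
        raise ValueError("truth mask marks no positives")
    finite = np.where(np.isfinite(scores), scores,
                      np.sign(scores) * (np.nanmax(np.abs(scores[np.isfinite(scores)]), initial=1.0) + 1.0))
    if np.all(finite == finite[0]):
        warnings.warn("all scores equal; PR-AUC equals the prevalence", stacklevel=2)
        return float(truth.mean())
    return float(average_precision_score(truth, finite))


def _generate(scenario, seed: int):
    if isinstance(scenario, LatentScenario):
        return gen_latent(replace(scenario, seed=seed))
    if isinstance(scenario, NonlinearScenario):
        return gen_nonlinear(replace(scenario, seed=seed))
    raise TypeError(f"unsupported scenario type {type(scenario).__name__}")


def run_scenario(
    scenario,
    methods=("filter", "mixture", "transformation"),
    replicates: int = 50,
    seed: int = 0,
    ntree: int = 100,
    k_repeats: int = 5,
    var_threshold: float = 0.8,
    pr: float = 0.05,
    alpha: float = 0.05,
    tuning_ntree: int | None = None,
    forest_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Benchmark the requested selection rules over replicated simulations.

    Returns ``(report, records)``: the report has one row per method with
    means and standard deviations of the four metrics; ``records`` holds the
    full per-replicate, per-dataset log.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    forest_kwargs = forest_kwargs or {}
    seeds = np.random.SeedSequence(seed).spawn(replicates)
    per_rep: dict[str, list[dict]] = {m: [] for m in methods}
    records: list[dict] = []

    for r, ss in enumerate(seeds):
        rep_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        data = _generate(scenario, rep_seed)
        params = ForestParams(ntree=ntree, seed=rep_seed, **forest_kwargs)
        try:
            models = choose_directions(data.datasets, params, var_threshold)
        except Exception as exc:  # noqa: BLE001 - replicate failures are logged, not fatal
            records.append({"replicate": r, "error": repr(exc)})
            continue
        mean_profiles = {
            tag: _mean_profile(profs, tag)
            for tag, profs in _model_profiles(models).items()
        }
        for method in methods:
            res = aggregate_and_select(
                models, method, datasets=data.datasets, params=params,
                k_repeats=k_repeats, pr=pr, alpha=alpha, tuning_ntree=tuning_ntree,
            )
            per_ds = []
            for tag, truth in data.truth.items():
                sel = res.selections[tag]
                rates = confusion_and_rates(sel.selected_mask, truth)
                prof = mean_profiles[tag]
                score = prof.tscore if method == "transformation" else prof.forest_imd
                rates["pr_auc"] = pr_auc(score, truth)
                rates["n_selected"] = int(sel.selected_mask.sum())
                rates["dataset"] = tag
                per_ds.append(rates)
                records.append({"replicate": r, "method": method, **rates})
            per_rep[method].append({
                "pr_auc": float(np.mean([d["pr_auc"] for d in per_ds])),
                "precision": float(np.mean([d["precision"] for d in per_ds])),
                "recall": float(np.mean([d["recall"] for d in per_ds])),
                "model_size": float(np.sum([d["n_selected"] for d in per_ds])),
            })

    rows = []
    for method in methods:
        reps = per_rep[method]
        row = {"method": method, "scenario": type(scenario).__name__, "replicates": len(reps)}
        for metric in METRICS:
            vals = np.array([d[metric] for d in reps])
            row[f"{metric}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{metric}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows), records
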