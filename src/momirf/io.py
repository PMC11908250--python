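"""Matrix and model serialization.

Matrices are delimited text with sample IDs in the first column and feature
IDs in the header row (samples x features).  Forests round-trip through a
versioned JSON schema with flattened node arrays, so a persisted run can be
replayed to identical IMD profiles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forest import MultivariateRandomForest, Tree

__all__ = [
    "read_matrix",
    "write_matrix",
    "forest_to_dict",
    "forest_from_dict",
    "save_forest",
    "load_forest",
    "write_results",
]

SCHEMA_VERSION = 1


def read_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a samples x features matrix, validating IDs and numeric content."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature ID {dup!r}")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        raise ValueError(f"{path}: non-numeric values in column {bad[0]!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(
            f"{path}: missing value at sample {row!r}, feature {col!r}; "
            "remove features with missing values before analysis"
        )
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep)


def _tree_to_dict(tree: Tree) -> dict:
    return {
        "feature": tree.feature.tolist(),
        "threshold": tree.threshold.tolist(),
        "msrv": tree.msrv.tolist(),
        "gq": tree.gq.tolist(),
        "depth": tree.depth.tolist(),
        "left": tree.left.tolist(),
        "right": tree.right.tolist(),
        "n_node": tree.n_node.tolist(),
        "inbag_count": tree.inbag_count.tolist(),
        "seed": tree.seed,
    }


def _tree_from_dict(d: dict) -> Tree:
    return Tree(
        d["feature"], d["threshold"], d["msrv"], d["gq"], d["depth"],
        d["left"], d["right"], d["n_node"], d["inbag_count"], d["seed"],
    )


def forest_to_dict(forest: MultivariateRandomForest) -> dict:
    """JSON-serializable forest (training matrices included for OOB replay)."""
    return {
        "schema": "momirf-forest",
        "version": SCHEMA_VERSION,
        "params": forest.get_params(),
        "feature_ids": list(forest.feature_ids_),
        "response_ids": list(forest.response_ids_),
        "X": np.asarray(forest.X_).tolist(),
        "Y": np.asarray(forest.Y_).tolist(),
        "trees": [_tree_to_dict(t) for t in forest.trees_],
    }


def forest_from_dict(d: dict) -> MultivariateRandomForest:
    if d.get("schema") != "momirf-forest":
        raise ValueError("not a momirf forest JSON document")
    est = MultivariateRandomForest(**d["params"])
    est.feature_ids_ = list(d["feature_ids"])
    est.response_ids_ = list(d["response_ids"])
    est.X_ = np.asarray(d["X"], dtype=float)
    est.Y_ = np.asarray(d["Y"], dtype=float)
    est.n_samples_, est.n_features_in_ = est.X_.shape
    est.n_responses_ = est.Y_.shape[1]
    est.trees_ = [_tree_from_dict(t) for t in d["trees"]]
    return est


def save_forest(forest: MultivariateRandomForest, path) -> None:
    Path(path).write_text(json.dumps(forest_to_dict(forest)))


def load_forest(path) -> MultivariateRandomForest:
    return forest_from_dict(json.loads(Path(path).read_text()))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_results(obj, path, params: dict | None = None) -> None:
    """Versioned JSON result document with a full parameter echo."""
    doc = {"schema": "momirf-result", "version": SCHEMA_VERSION,
           "params": params or {}, "result": obj}
    Path(path).write_text(json.dumps(doc, cls=_NumpyEncoder, indent=1))
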