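"""Boosted-tree diagnostic model and its evaluation protocol.

The classifier is a gradient-boosted decision-tree ensemble (binary
logistic objective).  The surrounding protocol — stratified train/test
split, exhaustive 5-fold grid search scored by held-out accuracy, an
error-minimizing probability threshold, the five named rates (accuracy,
sensitivity, omission diagnostic rate, specificity, mistake diagnosis
rate), the ROC curve with trapezoid AUC, and gain-share feature
importance — is implemented here; only the ensemble fit itself is
delegated to xgboost.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold, train_test_split

from .simulate import ClinicalDataset

__all__ = [
    "PAPER_OPTIMAL_PARAMS",
    "DEFAULT_GRID",
    "FittedModel",
    "MetricsReport",
    "split_train_test",
    "fit_model",
    "grid_search",
    "optimal_threshold",
    "classification_metrics",
    "roc_curve_points",
    "roc_auc",
    "gain_importance",
]

#: the reference hyper-parameter combination (the published optimum)
PAPER_OPTIMAL_PARAMS: dict = {
    "nrounds": 60,
    "eta": 0.2,
    "gamma": 0.5,
    "max_depth": 4,
    "min_child_weight": 1,
    "subsample": 0.55,
    "colsample_bytree": 1.0,
}

#: default exhaustive search grid (contains the reference optimum)
DEFAULT_GRID: dict[str, list] = {
    "nrounds": [20, 40, 60, 80, 100],
    "eta": [0.1, 0.2, 0.3],
    "gamma": [0, 0.5, 1],
    "max_depth": [3, 4, 5, 6],
    "min_child_weight": [1, 3, 5],
    "subsample": [0.55, 0.75, 1.0],
    "colsample_bytree": [0.55, 0.75, 1.0],
}


def _validate_params(params: dict) -> None:
    if not (0 < params["eta"] <= 1):
        raise ValueError("eta must be in (0, 1]")
    for key in ("subsample", "colsample_bytree"):
        if not (0 < params[key] <= 1):
            raise ValueError(f"{key} must be in (0, 1]")
    for key in ("nrounds", "max_depth"):
        if int(params[key]) != params[key] or params[key] < 1:
            raise ValueError(f"{key} must be a positive integer")
    if params["gamma"] < 0:
        raise ValueError("gamma must be non-negative")


@dataclass
class FittedModel:
    booster: xgb.Booster
    params: dict
    feature_names: list[str]
    threshold: float = 0.5

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        dmat = xgb.DMatrix(np.asarray(X, dtype=float), feature_names=self.feature_names)
        return self.booster.predict(dmat)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def save(self, path) -> None:
        self.booster.save_model(str(path))


@dataclass
class MetricsReport:
    """The five named rates plus AUC and the raw confusion counts.

    ``omission_rate`` is the false-negative rate (1 - sensitivity);
    ``mistake_rate`` is the false-positive rate (1 - specificity).  With a
    single observed class the undefined rates are NaN.
    """

    accuracy: float
    sensitivity: float
    omission_rate: float
    specificity: float
    mistake_rate: float
    auc: float
    tp: int
    fn: int
    tn: int
    fp: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "omission_rate": self.omission_rate,
            "specificity": self.specificity,
            "mistake_rate": self.mistake_rate,
            "auc": self.auc,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
        }


def split_train_test(
    dataset: ClinicalDataset, test_fraction: float = 0.3, seed: int = 0
) -> tuple[ClinicalDataset, ClinicalDataset]:
    """Stratified train/test split of the cohort."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    y = dataset.y
    idx = np.arange(len(dataset))
    tr, te = train_test_split(idx, test_size=test_fraction, stratify=y, random_state=seed)
    for part, name in ((tr, "train"), (te, "test")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"{name} split lost a class; adjust test_fraction")
    return dataset.subset(np.sort(tr)), dataset.subset(np.sort(te))


def _booster_params(params: dict, seed: int) -> dict:
    return {
        "objective": "binary:logistic",
        "base_score": 0.5,
        "tree_method": "exact",
        "eta": params["eta"],
        "gamma": params["gamma"],
        "max_depth": int(params["max_depth"]),
        "min_child_weight": params["min_child_weight"],
        "subsample": params["subsample"],
        "colsample_bytree": params["colsample_bytree"],
        "seed": seed,
        "nthread": 1,
    }


def fit_model(
    train: ClinicalDataset, params: dict | None = None, seed: int = 0
) -> FittedModel:
    """Train the boosted ensemble with the given hyper-parameters."""
    params = dict(PAPER_OPTIMAL_PARAMS if params is None else params)
    _validate_params(params)
    dtrain = xgb.DMatrix(train.X, label=train.y, feature_names=list(train.symptoms))
    booster = xgb.train(_booster_params(params, seed), dtrain, num_boost_round=int(params["nrounds"]))
    return FittedModel(booster=booster, params=params, feature_names=list(train.symptoms))


def grid_search(
    train: ClinicalDataset,
    grid: dict[str, list] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, float]:
    """Exhaustive hyper-parameter search by k-fold CV accuracy at threshold 0.5.

    Ties are broken toward fewer boosting rounds, then a shallower tree,
    then grid order.
    """
    grid = DEFAULT_GRID if grid is None else grid
    if any(len(v) == 0 for v in grid.values()) or not grid:
        raise ValueError("grid must be nonempty")
    keys = list(grid.keys())
    combos = [dict(zip(keys, values)) for values in itertools.product(*(grid[k_] for k_ in keys))]
    for combo in combos:
        full = {**PAPER_OPTIMAL_PARAMS, **combo}
        _validate_params(full)

    X, y = train.X, train.y
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best: tuple[float, float, float, int] | None = None  # (-acc, nrounds, depth, order)
    best_combo: dict = {}
    best_acc = -1.0
    for order, combo in enumerate(combos):
        params = {**PAPER_OPTIMAL_PARAMS, **combo}
        accs = []
        for tr, te in folds:
            dtrain = xgb.DMatrix(X[tr], label=y[tr], feature_names=list(train.symptoms))
            booster = xgb.train(
                _booster_params(params, seed), dtrain, num_boost_round=int(params["nrounds"])
            )
            scores = booster.predict(xgb.DMatrix(X[te], feature_names=list(train.symptoms)))
            accs.append(float(((scores >= 0.5).astype(int) == y[te]).mean()))
        acc = float(np.mean(accs))
        key = (-acc, params["nrounds"], params["max_depth"], order)
        if best is None or key < best:
            best, best_combo, best_acc = key, params, acc
    return best_combo, best_acc


def optimal_threshold(model: FittedModel, data: ClinicalDataset) -> float:
    """Probability cutoff in {0.01..0.99} minimizing misclassification error.

    Ties are broken toward the threshold closest to 0.5, then the smaller
    one.
    """
    scores = model.predict_proba(data.X)
    y = data.y
    grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
    best_t, best_key = 0.5, None
    for t in grid:
        err = float(((scores >= t).astype(int) != y).mean())
        key = (err, abs(t - 0.5), t)
        if best_key is None or key < best_key:
            best_key, best_t = key, float(t)
    return best_t


def classification_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Confusion counts and the five named rates; score >= threshold is positive."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    if n_pos and n_neg:
        _, auc = roc_auc(y, s)
    else:
        auc = float("nan")
    return MetricsReport(
        accuracy=(tp + tn) / len(y),
        sensitivity=sens,
        omission_rate=1.0 - sens if not math.isnan(sens) else float("nan"),
        specificity=spec,
        mistake_rate=1.0 - spec if not math.isnan(spec) else float("nan"),
        auc=auc,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def roc_curve_points(labels, scores) -> np.ndarray:
    """ROC points (fpr, tpr) from sweeping every unique score threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied score block
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.r_[distinct, len(y) - 1]
    tpr = tps[idx] / n_pos
    fpr = fps[idx] / n_neg
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


def roc_auc(labels, scores) -> tuple[np.ndarray, float]:
    """ROC point list and trapezoid AUC.

    The trapezoid rule over the tie-blocked ROC points equals the
    Mann-Whitney concordance probability with ties counted half.
    """
    pts = roc_curve_points(labels, scores)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


def gain_importance(model: FittedModel) -> pd.DataFrame:
    """Per-feature total split gain, normalized to shares, descending."""
    raw = model.booster.get_score(importance_type="total_gain")
    if not raw:
        raise ValueError("model has no splits; was it fitted?")
    total = sum(raw.values())
    rows = [{"feature": f, "gain_share": g / total} for f, g in raw.items()]
    table = pd.DataFrame(rows).sort_values("gain_share", ascending=False, kind="stable")
    return table.reset_index(drop=True)
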