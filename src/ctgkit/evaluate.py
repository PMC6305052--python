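"""Splitting, cross-validation, classification metrics and ROC/AUC.

The default protocol mirrors a 60/20/20 train/test/validation split for
the neural models and stratified 5-fold cross-validation for the feature
baselines.  The "Avg/total" row of the per-class report is the
support-weighted average, the classic classification-report convention.
Mean ROC curves are built by vertical averaging on a fixed 101-point
false-positive-rate grid; the mean AUC is the arithmetic mean of the
member AUCs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class SplitSpec:
    train_fraction: float = 0.60
    test_fraction: float = 0.20
    validation_fraction: float = 0.20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_fraction + self.test_fraction + self.validation_fraction
        if not np.isclose(total, 1.0):
            raise ValueError("split fractions must sum to 1")


@dataclass
class Metrics:
    precision: dict  # class -> value (NaN for absent classes)
    recall: dict
    f1: dict
    avg_precision: float  # support-weighted
    avg_recall: float
    avg_f1: float
    accuracy: float


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class EvalReport:
    protocol: str
    folds: list  # one dict per fold: metrics + roc
    mean_roc: Optional[ROCCurve]

    def summary(self) -> dict:
        accs = [f["metrics"].accuracy for f in self.folds]
        return {
            "protocol": self.protocol,
            "n_folds": len(self.folds),
            "accuracy_mean": float(np.mean(accs)),
            "accuracy_per_fold": [float(a) for a in accs],
            "auc_per_fold": [float(f["roc"].auc) for f in self.folds],
            "mean_auc": float(self.mean_roc.auc) if self.mean_roc else None,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, f in enumerate(self.folds):
            m = f["metrics"]
            rows.append(
                {
                    "fold": k,
                    "accuracy": m.accuracy,
                    "avg_precision": m.avg_precision,
                    "avg_recall": m.avg_recall,
                    "avg_f1": m.avg_f1,
                    "auc": f["roc"].auc,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base.tolist()


def split_dataset(labels, spec: SplitSpec | None = None):
    """Disjoint, exhaustive, stratified (train, test, validation) indices.

    Per-class sizes are the largest-remainder rounding of the class count
    times each fraction, so n=1000 with the defaults gives (600, 200, 200).
    """
    spec = spec or SplitSpec()
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    rng = np.random.default_rng(spec.seed)
    fractions = (spec.train_fraction, spec.test_fraction, spec.validation_fraction)

    groups = [y == c for c in np.unique(y)] if spec.stratified else [np.ones(n, bool)]
    train, test, val = [], [], []
    for mask in groups:
        idx = rng.permutation(np.flatnonzero(mask))
        n_tr, n_te, n_va = _largest_remainder(len(idx), fractions)
        if 0 in (n_tr, n_te, n_va):
            raise ValueError("a split would be empty for some class")
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr : n_tr + n_te])
        val.extend(idx[n_tr + n_te :])
    return (np.sort(train), np.sort(test), np.sort(val))


def kfold(labels, k: int = 5, seed: int = 0):
    """Stratified k-fold (train, test) index pairs; every record lands in
    exactly one test fold."""
    y = np.asarray(labels, dtype=int)
    if k > len(y):
        raise ValueError("k exceeds the number of records")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def compute_metrics(y_true, y_pred) -> Metrics:
    """Per-class precision/recall/F1 from the confusion table, plus the
    support-weighted averages and accuracy.

    A class absent from ``y_true`` gets NaN per-class metrics and zero
    weight in the averages.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length and nonempty")

    precision, recall, f1, support = {}, {}, {}, {}
    for c in (0, 1):
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        support[c] = tp + fn
        if support[c] == 0:
            precision[c] = recall[c] = f1[c] = float("nan")
            continue
        precision[c] = tp / (tp + fp) if tp + fp else 0.0
        recall[c] = tp / (tp + fn)
        denom = precision[c] + recall[c]
        f1[c] = 2 * precision[c] * recall[c] / denom if denom else 0.0

    total = sum(support.values())
    weighted = lambda d: float(
        sum(d[c] * support[c] for c in (0, 1) if support[c]) / total
    )
    return Metrics(
        precision=precision,
        recall=recall,
        f1=f1,
        avg_precision=weighted(precision),
        avg_recall=weighted(recall),
        avg_f1=weighted(f1),
        accuracy=float(np.mean(y_true == y_pred)),
    )


def roc_curve_auc(y_true, scores) -> ROCCurve:
    """Threshold-sweep ROC with trapezoidal AUC; tied scores collapse into
    a single step."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes in y_true")
    fpr, tpr, _ = _skm.roc_curve(y_true, scores)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr)))


def mean_roc(curves: list[ROCCurve]) -> ROCCurve:
    """Vertical averaging on the fixed FPR grid; mean AUC is the mean of
    the member AUCs."""
    if not curves:
        raise ValueError("need at least one curve")
    tprs = [np.interp(FPR_GRID, c.fpr, c.tpr) for c in curves]
    for t in tprs:
        t[0] = 0.0
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    return ROCCurve(
        fpr=FPR_GRID.copy(),
        tpr=mean_tpr,
        auc=float(np.mean([c.auc for c in curves])),
    )


def evaluate_model(
    make_predictor: Callable[[], "Predictor"],
    X,
    y,
    protocol: str = "kfold5",
    split: SplitSpec | None = None,
    seed: int = 0,
) -> EvalReport:
    """Run holdout or 5-fold CV evaluation of a predictor factory.

    ``make_predictor`` must return a fresh object with ``fit(X, y)``,
    ``predict(X)`` and ``score(X)`` (real-valued class-1 score).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = []
    if protocol == "holdout":
        tr, te, _va = split_dataset(y, split or SplitSpec(seed=seed))
        pairs = [(tr, te)]
    elif protocol in ("kfold5", "kfold"):
        pairs = kfold(y, k=5, seed=seed)
    else:
        raise ValueError("protocol must be 'holdout' or 'kfold5'")

    for tr, te in pairs:
        predictor = make_predictor()
        predictor.fit(X[tr], y[tr])
        y_pred = predictor.predict(X[te])
        scores = predictor.score(X[te])
        folds.append(
            {
                "metrics": compute_metrics(y[te], y_pred),
                "roc": roc_curve_auc(y[te], scores),
            }
        )
    return EvalReport(
        protocol=protocol,
        folds=folds,
        mean_roc=mean_roc([f["roc"] for f in folds]),
    )


class SklearnPredictor:
    """Adapter giving sklearn classifiers the evaluation protocol."""

    def __init__(self, factory: Callable):
        self._factory = factory
        self._clf = None

    def fit(self, X, y):
        self._clf = self._factory()
        self._clf.fit(X, y)
        return self

    def predict(self, X):
        return self._clf.predict(X)

    def score(self, X):
        if hasattr(self._clf, "predict_proba"):
            return self._clf.predict_proba(X)[:, 1]
        return self._clf.decision_function(X)
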