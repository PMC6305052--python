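"""Feature-table control classifiers: RBF-SVM and random forest.

The SVM uses the grid-searched hyperparameters kernel=rbf, C=1000,
gamma=0.0001 with all other settings at their defaults.  Features are
z-scored on the training data before the SVM (with gamma=1e-4 an RBF
kernel on raw clinical scales would be nearly constant); the forest gets
the raw features.  Both expose real-valued scores for ROC analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

DEFAULT_SVM_HYPER = {"kernel": "rbf", "C": 1000.0, "gamma": 1e-4}


@dataclass
class GridSearchSpec:
    kernels: tuple = ("rbf", "linear")
    C: tuple = (1.0, 10.0, 100.0, 1000.0)
    gamma: tuple = (1e-2, 1e-3, 1e-4, 1e-5)
    folds: int = 5

    def __post_init__(self) -> None:
        if not (self.kernels and self.C and self.gamma):
            raise ValueError("candidate lists must be nonempty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def _check_training_inputs(X: np.ndarray, y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    constant = np.flatnonzero(X.std(axis=0) == 0)
    if len(constant):
        warnings.warn(
            f"constant feature column(s) {constant.tolist()}; proceeding",
            stacklevel=3,
        )


def fit_svm(X, y, kernel: str = "rbf", C: float = 1000.0, gamma: float = 1e-4):
    """Standardized RBF-SVM; ``decision_function`` provides ROC scores."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_training_inputs(X, y)
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C, gamma=gamma)),
        ]
    )
    return clf.fit(X, y)


def fit_rf(X, y, n_estimators: int = 100, seed: int = 0):
    """Random forest with class-probability outputs for ROC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_training_inputs(X, y)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    return clf.fit(X, y)


def grid_search(X, y, spec: GridSearchSpec | None = None, seed: int = 0) -> dict:
    """Exhaustive hyperparameter search by inner-CV accuracy.

    Ties are broken toward smaller C, then larger gamma (the smoother
    model).  Linear kernels ignore gamma and are evaluated once per C.
    """
    spec = spec or GridSearchSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if spec.folds > counts.min():
        raise ValueError("fold count exceeds the support of a class")
    cv = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=seed)

    candidates = []
    for kernel, C in itertools.product(spec.kernels, spec.C):
        gammas = spec.gamma if kernel == "rbf" else (spec.gamma[0],)
        for gamma in gammas:
            candidates.append({"kernel": kernel, "C": C, "gamma": gamma})

    best, best_score = None, -np.inf
    for hyper in candidates:
        clf = Pipeline(
            [("scale", StandardScaler()), ("svm", SVC(**hyper))]
        )
        score = cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean()
        better = score > best_score + 1e-12
        tie = abs(score - best_score) <= 1e-12
        if better or (
            tie
            and (hyper["C"], -hyper["gamma"]) < (best["C"], -best["gamma"])
        ):
            best, best_score = dict(hyper), score
    best["cv_accuracy"] = float(best_score)
    return best
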