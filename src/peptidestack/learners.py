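"""The 13 baseline learning algorithms and grid tuning by cross-validated MCC.

Nine algorithms carry a one-parameter search grid (tree counts for the
ensemble methods, regularization cost for the linear/kernel models, hidden
layer width for the MLP); decision tree, k-nearest-neighbour, naive Bayes
and partial least squares run with documented fixed defaults. Tuning
evaluates every grid point by stratified k-fold cross-validation, scores the
pooled out-of-fold confidences by MCC, refits the winner on all data, and
breaks ties by the first (smallest) grid value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from peptidestack.evaluation import ConfusionCounts, mcc_from_counts
from peptidestack.features import FeatureMatrix

ALGORITHMS = (
    "ADA", "DT", "ET", "KNN", "LGBM", "LR", "MLP", "NB", "PLS",
    "SVMLN", "SVMRBF", "RF", "XGB",
)

#: Hyperparameter search grids for the nine tuned algorithms. The other
#: four (DT, KNN, NB, PLS) use fixed defaults documented in _build().
GRIDS: dict[str, dict[str, list]] = {
    "ADA": {"n_estimators": [20, 50, 100, 200, 500]},
    "ET": {"n_estimators": [20, 50, 100, 200, 500]},
    "LGBM": {"n_estimators": [20, 50, 100, 200, 500]},
    "LR": {"C": [0.001, 0.01, 0.1, 1, 10, 100]},
    "MLP": {"hidden_layer_sizes": [20, 50, 100, 200, 500]},
    "RF": {"n_estimators": [20, 50, 100, 200, 500]},
    "SVMLN": {"C": [2.0**k for k in range(0, 6)]},
    "SVMRBF": {"C": [2.0**k for k in range(-4, 5)]},
    "XGB": {"n_estimators": [20, 50, 100, 200, 500]},
}


class PLSClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier on top of partial-least-squares regression.

    Labels are coded {0,1}; the predicted response, clipped to [0,1], is the
    positive-class confidence and the decision rule is confidence >=
    threshold. The component count is capped by the data at fit time so the
    same configuration works on small masked feature sets.
    """

    def __init__(self, n_components: int = 2, threshold: float = 0.5):
        self.n_components = n_components
        self.threshold = threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.classes_ = np.array([0, 1])
        # zero-variance columns carry no signal and break the PLS deflation;
        # with no informative column left, fall back to the base rate
        self.keep_ = X.max(axis=0) > X.min(axis=0)
        if not self.keep_.any():
            self.pls_ = None
            self.constant_ = float(y.mean())
            return self
        X = X[:, self.keep_]
        cap = max(1, min(self.n_components, X.shape[1], X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=cap)
        self.pls_.fit(X, y)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if self.pls_ is None:
            return np.full(X.shape[0], self.constant_)
        return self.pls_.predict(X[:, self.keep_]).ravel()

    def predict_proba(self, X):
        conf = np.clip(self.decision_function(X), 0.0, 1.0)
        return np.column_stack([1.0 - conf, conf])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


def _build(algorithm: str, params: dict, seed: int):
    """Construct an unfitted estimator for one algorithm + grid point."""
    if algorithm == "ADA":
        return AdaBoostClassifier(random_state=seed, **params)
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm == "ET":
        return ExtraTreesClassifier(random_state=seed, **params)
    if algorithm == "KNN":
        return KNeighborsClassifier(n_neighbors=params.get("n_neighbors", 5))
    if algorithm == "LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1, **params)
    if algorithm == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if algorithm == "MLP":
        width = params.get("hidden_layer_sizes", 100)
        if isinstance(width, int):
            width = (width,)
        return Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(hidden_layer_sizes=width, max_iter=500,
                                  random_state=seed)),
        ])
    if algorithm == "NB":
        return GaussianNB()
    if algorithm == "PLS":
        return PLSClassifier(n_components=params.get("n_components", 2))
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "SVMLN":
        # probability=True fits Platt scaling on internal CV so the model
        # can emit the confidences the stacking layer needs
        return SVC(kernel="linear", probability=True, random_state=seed, **params)
    if algorithm == "SVMRBF":
        return SVC(kernel="rbf", gamma="scale", probability=True,
                   random_state=seed, **params)
    if algorithm == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, verbosity=0,
                             eval_metric="logloss", **params)
    raise KeyError(f"unknown algorithm {algorithm!r}")


@dataclass(frozen=True)
class LearnerSpec:
    """One algorithm plus its (possibly empty) hyperparameter grid."""

    algorithm: str
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise KeyError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            object.__setattr__(self, "grid", GRIDS.get(self.algorithm, {}))

    def grid_points(self) -> list[dict]:
        if not self.grid:
            return [{}]
        (name, values), = self.grid.items()  # single-parameter grids
        return [{name: v} for v in values]


@dataclass
class TrainedLearner:
    spec: LearnerSpec
    chosen_params: dict
    estimator: object
    n_features: int
    cv_mcc: float
    data_hash: str
    seed: int

    def predict_confidence(self, X) -> np.ndarray:
        X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"{self.spec.algorithm}: expected {self.n_features} features, "
                f"got {X.shape[1]}"
            )
        return _confidence(self.estimator, X)

    def manifest(self) -> dict:
        return {
            "algorithm": self.spec.algorithm,
            "grid": self.spec.grid,
            "chosen_params": self.chosen_params,
            "cv_mcc": self.cv_mcc,
            "n_features": self.n_features,
            "seed": self.seed,
            "data_hash": self.data_hash,
        }


def _confidence(estimator, X: np.ndarray) -> np.ndarray:
    conf = estimator.predict_proba(X)[:, 1]
    return np.clip(np.asarray(conf, dtype=float), 0.0, 1.0)


def _check_Xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y length")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return X, y


def _pooled_cv_mcc(estimator, X, y, k, seed) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx])
        oof[test_idx] = _confidence(model, X[test_idx])
    pred = (oof >= 0.5).astype(int)
    counts = ConfusionCounts(
        tp=int(((y == 1) & (pred == 1)).sum()),
        tn=int(((y == 0) & (pred == 0)).sum()),
        fp=int(((y == 0) & (pred == 1)).sum()),
        fn=int(((y == 1) & (pred == 0)).sum()),
    )
    return mcc_from_counts(counts)


def tune_and_fit(
    spec: LearnerSpec | str,
    X,
    y,
    k: int = 10,
    seed: int = 0,
) -> TrainedLearner:
    """Grid-tune one algorithm by stratified k-fold CV MCC and refit on all
    data. Ties go to the earliest grid point, i.e. the smallest value."""
    if isinstance(spec, str):
        spec = LearnerSpec(spec)
    X, y = _check_Xy(X, y)
    k = min(k, int(np.bincount(y).min()))
    if k < 2:
        raise ValueError("not enough samples per class for cross-validated tuning")
    best_params, best_mcc = None, -np.inf
    for params in spec.grid_points():
        mcc = _pooled_cv_mcc(_build(spec.algorithm, params, seed), X, y, k, seed)
        if mcc > best_mcc:
            best_params, best_mcc = params, mcc
    estimator = _build(spec.algorithm, best_params, seed)
    estimator.fit(X, y)
    return TrainedLearner(
        spec=spec,
        chosen_params=best_params,
        estimator=estimator,
        n_features=X.shape[1],
        cv_mcc=float(best_mcc),
        data_hash=joblib.hash((X, y)),
        seed=seed,
    )
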