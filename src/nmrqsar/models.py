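"""Model harness: random forest, k-NN and SVM learners with the evaluation
protocols used throughout the toolkit (out-of-bag estimation, ten-fold
cross-validation, class-weight rebalancing, C tuning for the SVM).

The learners delegate to scikit-learn; the contract fixed here is the
hyperparameter surface (500 trees, mtry = sqrt(p) for classification or
p/3 for regression, k = 10 inverse-distance-weighted neighbors, RBF SVM
with gamma = 1/p), the out-of-bag semantics, vote-fraction class
probabilities, and the zero-distance k-NN short-circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR

from .metrics import (
    ConfusionCounts,
    classification_report,
    regression_report,
)

ALGORITHMS = ("rf", "knn", "svm")
TASKS = ("classification", "regression")

#: Default SVM cost grid spanning the tuned 10-1000 range.
DEFAULT_C_GRID = (10.0, 50.0, 100.0, 250.0, 500.0, 1000.0)


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    algorithm: str
    task: str
    n_trees: int = 500
    mtry: int | None = None          # default sqrt(p) / p/3 resolved at fit time
    k: int = 10
    knn_weighting: str = "distance"  # inverse-distance neighbor weighting
    C: float = 100.0
    gamma: float | str = "auto"      # "auto" = 1/p
    class_weights: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ModelError(f"unknown algorithm {self.algorithm!r}")
        if self.task not in TASKS:
            raise ModelError(f"unknown task {self.task!r}")


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: Any
    classes: np.ndarray | None = None
    oob_predictions: np.ndarray | None = None   # rf only
    oob_probabilities: np.ndarray | None = None  # rf classification only
    _train: tuple | None = field(default=None, repr=False)

    @property
    def importances_impurity(self) -> np.ndarray | None:
        return getattr(self.estimator, "feature_importances_", None)

    def importances(self, kind: str = "permutation", n_repeats: int = 1,
                    X=None, y=None) -> np.ndarray:
        """Per-descriptor importances for a fitted forest.

        ``permutation`` is the out-of-bag mean decrease in accuracy
        (classification) or in negative MSE (regression): for each tree,
        each descriptor used by that tree is shuffled among the tree's
        out-of-bag samples and the accuracy drop is averaged over trees.
        ``impurity`` returns the forest's mean decrease in impurity.
        ``heldout`` scores whole-forest permutation importance on supplied
        (X, y) instead.
        """
        if self.spec.algorithm != "rf":
            raise ModelError("importances are defined for random forests only")
        if kind == "impurity":
            return self.estimator.feature_importances_
        if kind == "heldout":
            if X is None or y is None:
                raise ModelError("heldout importances need X and y")
            result = permutation_importance(
                self.estimator, X, y, n_repeats=max(n_repeats, 2),
                random_state=self.spec.seed,
            )
            return result.importances_mean
        if kind != "permutation":
            raise ModelError(f"unknown importance kind {kind!r}")
        if self._train is None:
            raise ModelError("no training data retained for OOB importances")
        return oob_permutation_importance(self, n_repeats=n_repeats)


def oob_permutation_importance(model: FittedModel, n_repeats: int = 1) -> np.ndarray:
    """Out-of-bag permutation importance of a fitted random forest.

    For every tree: score its out-of-bag samples, then re-score them with
    each descriptor used by the tree permuted (descriptors a tree never
    splits on cannot change its predictions and contribute 0).  The
    importance of a descriptor is the mean score decrease over all trees
    -- accuracy for classification, negative MSE for regression.
    """
    from sklearn.utils import check_random_state

    if model.spec.algorithm != "rf":
        raise ModelError("OOB permutation importance applies to random forests")
    X, y = model._train
    n, p = X.shape
    forest = model.estimator
    classification = model.spec.task == "classification"
    rng = np.random.default_rng(model.spec.seed)
    if classification:
        y_num = y
    else:
        y_num = np.asarray(y, dtype=float)

    importances = np.zeros(p)
    for tree in forest.estimators_:
        # reproduce the bootstrap draw sklearn made for this tree
        sample_idx = check_random_state(tree.random_state).randint(0, n, n)
        oob = np.setdiff1d(np.arange(n), sample_idx, assume_unique=False)
        if oob.size == 0:
            continue
        X_oob = X[oob]
        y_oob = y_num[oob]
        pred = tree.predict(X_oob)
        if classification:
            # sub-trees predict label-encoded class indices
            base = float(np.mean(forest.classes_[pred.astype(int)] == y_oob))
        else:
            base = -float(np.mean((pred - y_oob) ** 2))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            drop = 0.0
            for _ in range(n_repeats):
                X_perm = X_oob.copy()
                X_perm[:, j] = X_perm[rng.permutation(oob.size), j]
                pred_j = tree.predict(X_perm)
                if classification:
                    score = float(np.mean(forest.classes_[pred_j.astype(int)] == y_oob))
                else:
                    score = -float(np.mean((pred_j - y_oob) ** 2))
                drop += base - score
            importances[j] += drop / n_repeats
    return importances / len(forest.estimators_)


def _resolve_mtry(spec: ModelSpec, p: int):
    if spec.mtry is not None:
        return spec.mtry
    if spec.task == "classification":
        return max(1, int(round(np.sqrt(p))))
    return max(1, int(p // 3))


def _build_estimator(spec: ModelSpec, p: int):
    if spec.algorithm == "rf":
        kwargs = dict(
            n_estimators=spec.n_trees,
            max_features=_resolve_mtry(spec, p),
            oob_score=True,
            random_state=spec.seed,
            bootstrap=True,
        )
        if spec.task == "classification":
            return RandomForestClassifier(class_weight=spec.class_weights, **kwargs)
        return RandomForestRegressor(**kwargs)
    if spec.algorithm == "knn":
        kwargs = dict(
            n_neighbors=spec.k, weights=spec.knn_weighting, metric="euclidean"
        )
        cls = KNeighborsClassifier if spec.task == "classification" else KNeighborsRegressor
        return cls(**kwargs)
    gamma = spec.gamma if spec.gamma != "auto" else 1.0 / p
    if spec.task == "classification":
        return SVC(kernel="rbf", C=spec.C, gamma=gamma, class_weight=spec.class_weights,
                   random_state=spec.seed)
    return SVR(kernel="rbf", C=spec.C, gamma=gamma)


def fit(spec: ModelSpec, X, y) -> FittedModel:
    """Fit the configured learner; deterministic given the spec seed.

    Random forests additionally expose per-sample out-of-bag predictions
    (and vote probabilities for classification).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ModelError("X and y must align")
    if X.shape[0] < 2:
        raise ModelError("need at least 2 samples")
    if not np.isfinite(X).all():
        raise ModelError("X contains non-finite values")
    if spec.task == "classification" and np.unique(y).size < 2:
        raise ModelError("classification needs at least 2 classes")

    est = _build_estimator(spec, X.shape[1])
    est.fit(X, y)
    fitted = FittedModel(spec=spec, estimator=est, _train=(X, y))
    if spec.task == "classification":
        fitted.classes = est.classes_ if hasattr(est, "classes_") else np.unique(y)
    if spec.algorithm == "rf":
        if spec.task == "classification":
            proba = est.oob_decision_function_
            fitted.oob_probabilities = proba
            with np.errstate(invalid="ignore"):
                idx = np.nanargmax(proba, axis=1)
            fitted.oob_predictions = est.classes_[idx]
        else:
            fitted.oob_predictions = est.oob_prediction_
    return fitted


def predict(model: FittedModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model._train[0].shape[1]:
        raise ModelError(
            f"dimension mismatch: got {X.shape[1] if X.ndim == 2 else '?'} features, "
            f"expected {model._train[0].shape[1]}"
        )
    return model.estimator.predict(X)


def predict_proba(model: FittedModel, X, positive=None) -> np.ndarray:
    """Class probabilities (vote fractions for the forest; inverse-distance
    vote shares for k-NN).  If ``positive`` is given, return the
    probability column of that class only."""
    if model.spec.task != "classification":
        raise ModelError("probabilities are defined for classification only")
    if not hasattr(model.estimator, "predict_proba"):
        raise ModelError(f"{model.spec.algorithm} does not expose class probabilities")
    X = np.asarray(X, dtype=float)
    proba = model.estimator.predict_proba(X)
    if positive is None:
        return proba
    (col,) = np.where(model.classes == positive)[0]
    return proba[:, col]


def rebalance_weights(class_counts: dict) -> dict:
    """Class weights inversely proportional to counts, normalized so each
    class contributes the same total weight (a 50:50 effective balance).

    The weighted mass of class c is ``weight_c * count_c = total / n_classes``
    for every class.
    """
    if len(class_counts) < 2:
        raise ModelError("need at least two classes")
    if any(c <= 0 for c in class_counts.values()):
        raise ModelError("every class must be non-empty")
    total = sum(class_counts.values())
    k = len(class_counts)
    return {label: total / (k * count) for label, count in class_counts.items()}


@dataclass
class EvaluationReport:
    task: str
    pooled: dict
    per_fold: list


def cross_validate(spec: ModelSpec, X, y, folds: int = 10, seed: int = 0,
                   positive=None) -> EvaluationReport:
    """K-fold cross-validation (stratified for classification) with pooled
    out-of-fold metrics; deterministic under the given seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if folds < 2:
        raise ModelError("folds must be >= 2")
    if folds > n:
        raise ModelError(f"folds={folds} exceeds n={n}")
    if spec.task == "classification":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X)

    pooled_pred = np.empty(n, dtype=y.dtype if spec.task == "classification" else float)
    per_fold = []
    for train_idx, test_idx in split:
        fold_model = fit(spec, X[train_idx], y[train_idx])
        pred = predict(fold_model, X[test_idx])
        pooled_pred[test_idx] = pred
        if spec.task == "classification":
            pos = positive if positive is not None else np.unique(y)[0]
            try:
                cm = ConfusionCounts.from_labels(y[test_idx], pred, pos)
                per_fold.append(classification_report(cm))
            except Exception:
                per_fold.append(None)
        else:
            per_fold.append(regression_report(y[test_idx], pred))

    if spec.task == "classification":
        pos = positive if positive is not None else np.unique(y)[0]
        cm = ConfusionCounts.from_labels(y, pooled_pred, pos)
        pooled = classification_report(cm)
    else:
        rep = regression_report(y, pooled_pred)
        pooled = {"report": rep, "rounded": rep.rounded()}
    return EvaluationReport(task=spec.task, pooled=pooled, per_fold=per_fold)


def tune_c(spec: ModelSpec, X, y, grid=DEFAULT_C_GRID, folds: int = 10,
           seed: int = 0, positive=None) -> tuple[float, dict]:
    """Pick the SVM cost C from a grid by cross-validated performance
    (pooled accuracy for classification, negative RMSE for regression);
    ties go to the smallest C.  Returns (best C, score per C)."""
    if spec.algorithm != "svm":
        raise ModelError("tune_c applies to svm specs")
    grid = sorted(set(float(c) for c in grid))
    if not grid:
        raise ModelError("empty C grid")
    scores = {}
    for c in grid:
        trial = ModelSpec(**{**spec.__dict__, "C": c})
        report = cross_validate(trial, X, y, folds=folds, seed=seed, positive=positive)
        if spec.task == "classification":
            scores[c] = report.pooled["raw"]["q"]
        else:
            scores[c] = -report.pooled["report"].rmse
    best = max(grid, key=lambda c: (scores[c], -c))
    return best, scores
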