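"""The two-stage predictor.

Stage 1 is an RBF-kernel support-vector classifier (one-against-one
multi-class with pairwise-coupled class probabilities) that assigns
high / medium / low soluble-expression class.  Stage 2 holds one
epsilon-SVR per class, each trained only on its own class's instances; the
regressor of the *predicted* class outputs the real-valued yield in mg/l
(misclassifications are not corrected downstream).  Hyperparameters come
from an exhaustive grid search with cross validation.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import SVC, SVR

from .errors import (
    FoldError,
    InvalidArgumentError,
    ModelStateError,
    NoSignalError,
    UncoveredClassError,
)
from .evaluation import CLASS_ORDER, ConfusionCounts, macro_metrics, stratified_folds
from .feature_selection import forward_select
from .preprocessing import StandardizationModel, apply_standardizer, fit_standardizer
from .sequence_features import (
    FeatureRegistry,
    PropertyPredictorSuite,
    SequenceRecord,
    extract_matrix,
    full_feature_vector,
    subset_feature_names,
)

TASKS = ("classification", "reg_high", "reg_medium", "reg_low")
_CLASS_TO_TASK = {"high": "reg_high", "medium": "reg_medium", "low": "reg_low"}

LOW_THRESHOLD = 0.5
HIGH_THRESHOLD = 100.0


def yield_to_class(value: float) -> str:
    """Map a soluble yield (mg/l) to its expression class.

    Boundaries are inclusive on both thresholds: low iff yield <= 0.5,
    high iff yield >= 100, medium in between.
    """
    value = float(value)
    if not value > 0:
        raise InvalidArgumentError(f"yield must be positive, got {value}")
    if value <= LOW_THRESHOLD:
        return "low"
    if value >= HIGH_THRESHOLD:
        return "high"
    return "medium"


def default_svc_grid() -> list[dict]:
    """C in 2^-5..2^15, gamma in 2^-15..2^3 (exponent step 2)."""
    return [
        {"C": 2.0**c, "gamma": 2.0**g}
        for c in range(-5, 16, 2)
        for g in range(-15, 4, 2)
    ]


def default_svr_grid() -> list[dict]:
    return [
        {"C": 2.0**c, "gamma": 2.0**g, "epsilon": eps}
        for c in range(-5, 16, 2)
        for g in range(-15, 4, 2)
        for eps in (0.01, 0.1, 1.0)
    ]


@dataclass(frozen=True)
class ModelConfig:
    """Training configuration for the two-stage model."""

    feature_mode: str = "cfs"  # cfs | preset | fixed
    fixed_features: dict | None = None  # task -> list of feature names
    svc_grid: tuple = tuple()  # empty -> default grid
    svr_grid: tuple = tuple()
    grid_cv_folds: int = 5
    max_subset_size: int = 20
    tie_tol: float = 1e-6
    seed: int = 0
    high_cap: float = 10000.0  # documented cap above the largest curated yield
    yield_floor: float = 1e-3
    log_targets: bool = False  # fit regressors on log10 yields instead of raw mg/l

    def svc_points(self) -> list[dict]:
        return list(self.svc_grid) or default_svc_grid()

    def svr_points(self) -> list[dict]:
        return list(self.svr_grid) or default_svr_grid()


@dataclass
class TaskModel:
    """One fitted sub-model: feature subset, standardizer, estimator."""

    features: list[str]
    indices: np.ndarray
    standardizer: StandardizationModel
    estimator: object
    params: dict
    n_train: int


@dataclass
class TwoStageModel:
    """Stage-1 classifier plus three class-specific regressors."""

    tasks: dict = field(default_factory=dict)
    config: ModelConfig | None = None
    registry_config: dict | None = None
    metadata: dict = field(default_factory=dict)

    def assert_fitted(self) -> None:
        missing = [t for t in TASKS if t not in self.tasks]
        if missing:
            raise ModelStateError(f"model not trained: missing sub-models {missing}")


@dataclass(frozen=True)
class Prediction:
    """Class label, probability triple (high, low, medium) and yield."""

    label: str
    probabilities: tuple[float, float, float]
    yield_mg_per_l: float


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


def _plain_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def grid_search(
    X: np.ndarray,
    y: Sequence,
    param_grid: Iterable[dict],
    cv_folds: int = 5,
    seed: int = 0,
    task: str | None = None,
) -> tuple[dict, float]:
    """Exhaustive grid search with cross validation.

    Classification points (no ``epsilon`` key) are scored by pooled
    out-of-fold macro average accuracy (higher is better); regression
    points by pooled RMSE (lower is better).  Deterministic given the seed;
    ties keep the earliest grid point.  Returns (best_params, best_score).
    """
    X = np.asarray(X, dtype=np.float64)
    y_arr = np.asarray(y)
    grid = list(param_grid)
    if not grid:
        raise InvalidArgumentError("empty parameter grid")
    n = X.shape[0]
    if n < cv_folds:
        raise FoldError(f"grid search needs n >= cv_folds ({n} < {cv_folds})")
    if task is None:
        task = "regression" if "epsilon" in grid[0] else "classification"

    rng = np.random.default_rng(seed)
    if task == "classification":
        min_class = min(np.sum(y_arr == c) for c in set(y_arr.tolist()))
        folds = stratified_folds(y_arr, max(2, min(cv_folds, int(min_class))), rng)
    else:
        folds = _plain_folds(n, max(2, min(cv_folds, n)), rng)

    best_params, best_score = None, None
    for params in grid:
        oof = np.empty(n, dtype=object if task == "classification" else np.float64)
        for fold in folds:
            if fold.size == 0:
                continue
            train_idx = np.setdiff1d(np.arange(n), fold)
            if task == "classification":
                est = SVC(kernel="rbf", random_state=seed, **params)
            else:
                est = SVR(kernel="rbf", **params)
            est.fit(X[train_idx], y_arr[train_idx])
            oof[fold] = est.predict(X[fold])
        if task == "classification":
            counts = ConfusionCounts.from_labels(y_arr, oof.astype(str))
            score = macro_metrics(counts)["average_accuracy"]
            better = best_score is None or score > best_score
        else:
            score = float(np.sqrt(np.mean((oof - y_arr.astype(np.float64)) ** 2)))
            better = best_score is None or score < best_score
        if better:
            best_params, best_score = dict(params), score
    return best_params, best_score


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _select_task_features(
    task: str,
    X_rows: np.ndarray,
    target,
    config: ModelConfig,
    registry: FeatureRegistry,
    classification: bool,
) -> list[str]:
    names = registry.all_names
    if config.feature_mode == "preset":
        return subset_feature_names(task, registry)
    if config.feature_mode == "fixed":
        if not config.fixed_features or task not in config.fixed_features:
            raise InvalidArgumentError(
                f"feature_mode='fixed' but no fixed_features entry for task {task!r}"
            )
        features = list(config.fixed_features[task])
        if not features:
            raise InvalidArgumentError(f"empty fixed feature list for task {task!r}")
        return features
    if config.feature_mode != "cfs":
        raise InvalidArgumentError(f"unknown feature_mode {config.feature_mode!r}")
    std = fit_standardizer(X_rows)
    Xs = apply_standardizer(std, X_rows)
    selected = forward_select(
        Xs,
        target,
        max_subset_size=config.max_subset_size,
        tie_tol=config.tie_tol,
        classification=classification,
    )
    if not selected:
        raise NoSignalError(f"feature selection found no informative feature for {task!r}")
    return [names[i] for i in selected]


def train(
    dataset,
    config: ModelConfig | None = None,
    registry: FeatureRegistry | None = None,
    suite: PropertyPredictorSuite | None = None,
    matrix: np.ndarray | None = None,
) -> TwoStageModel:
    """Train stage-1 on all instances and each regressor on its class only."""
    config = config or ModelConfig()
    registry = registry or FeatureRegistry()
    suite = suite or PropertyPredictorSuite.default()

    records = [rec for rec, _ in dataset.records]
    yields = dataset.yields()
    labels = np.array([yield_to_class(v) for v in yields])
    short = [c for c in CLASS_ORDER if int(np.sum(labels == c)) < 2]
    if short:
        raise UncoveredClassError(short)

    if matrix is None:
        matrix = extract_matrix(records, registry, suite)
    names = registry.all_names

    model = TwoStageModel(
        config=config,
        registry_config=registry.to_config(),
        metadata={"seed": config.seed, "n_train": len(records)},
    )

    # Stage 1: multi-class SVC on all instances.
    features = _select_task_features(
        "classification", matrix, labels, config, registry, classification=True
    )
    idx = np.array([registry.index_of(f) for f in features], dtype=np.int64)
    std = fit_standardizer(matrix[:, idx], tuple(features))
    Xs = apply_standardizer(std, matrix[:, idx])
    params, _ = grid_search(
        Xs, labels, config.svc_points(), config.grid_cv_folds, config.seed,
        task="classification",
    )
    svc = SVC(kernel="rbf", probability=True, random_state=config.seed, **params)
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates probability=True in favour of
        # CalibratedClassifierCV; pairwise coupling on the OvO machine is
        # exactly the behaviour this model wants, so keep it until removal
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(Xs, labels)
    model.tasks["classification"] = TaskModel(
        features, idx, std, svc, params, len(records)
    )

    # Stage 2: one epsilon-SVR per class, trained on that class only.
    for cls_label in CLASS_ORDER:
        task = _CLASS_TO_TASK[cls_label]
        rows = np.flatnonzero(labels == cls_label)
        y_cls = yields[rows]
        target = np.log10(y_cls) if config.log_targets else y_cls
        features = _select_task_features(
            task, matrix[rows], target, config, registry, classification=False
        )
        idx = np.array([registry.index_of(f) for f in features], dtype=np.int64)
        std = fit_standardizer(matrix[np.ix_(rows, idx)], tuple(features))
        Xs = apply_standardizer(std, matrix[np.ix_(rows, idx)])
        params, _ = grid_search(
            Xs, target, config.svr_points(),
            min(config.grid_cv_folds, rows.size), config.seed, task="regression",
        )
        svr = SVR(kernel="rbf", **params)
        svr.fit(Xs, target)
        model.tasks[task] = TaskModel(features, idx, std, svr, params, int(rows.size))

    model.assert_fitted()
    return model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _class_interval(label: str, config: ModelConfig) -> tuple[float, float]:
    if label == "low":
        return (config.yield_floor, LOW_THRESHOLD)
    if label == "medium":
        return (
            math.nextafter(LOW_THRESHOLD, math.inf),
            math.nextafter(HIGH_THRESHOLD, -math.inf),
        )
    return (HIGH_THRESHOLD, config.high_cap)


def regress_raw(model: TwoStageModel, cls_label: str, X_full: np.ndarray) -> np.ndarray:
    """Unclamped yield predictions of one class's regressor (mg/l)."""
    model.assert_fitted()
    task = model.tasks[_CLASS_TO_TASK[cls_label]]
    Xs = apply_standardizer(task.standardizer, np.asarray(X_full)[:, task.indices])
    out = np.asarray(task.estimator.predict(Xs), dtype=np.float64)
    if model.config is not None and model.config.log_targets:
        with np.errstate(over="ignore"):  # extreme outputs clamp downstream anyway
            out = 10.0**out
    return out


def predict_features(model: TwoStageModel, X_full: np.ndarray) -> list[Prediction]:
    """Predict from pre-extracted full feature vectors (n x 7,903)."""
    model.assert_fitted()
    config = model.config or ModelConfig()
    X_full = np.atleast_2d(np.asarray(X_full, dtype=np.float64))

    cls_task = model.tasks["classification"]
    Xs = apply_standardizer(cls_task.standardizer, X_full[:, cls_task.indices])
    svc = cls_task.estimator
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        proba = np.asarray(svc.predict_proba(Xs), dtype=np.float64)
    proba = proba / proba.sum(axis=1, keepdims=True)
    svc_classes = list(svc.classes_)
    col = {c: svc_classes.index(c) for c in CLASS_ORDER}

    predictions: list[Prediction] = []
    for i in range(X_full.shape[0]):
        triple = tuple(float(proba[i, col[c]]) for c in CLASS_ORDER)
        # the label is the argmax of the coupled probabilities, so the
        # reported triple and label can never disagree
        label = CLASS_ORDER[int(np.argmax(triple))]
        raw = float(regress_raw(model, label, X_full[i : i + 1])[0])
        lo, hi = _class_interval(label, config)
        predictions.append(Prediction(label, triple, float(np.clip(raw, lo, hi))))
    return predictions


def predict(
    model: TwoStageModel,
    record: SequenceRecord,
    registry: FeatureRegistry | None = None,
    suite: PropertyPredictorSuite | None = None,
) -> Prediction:
    """Predict class, class probabilities and yield for one sequence."""
    model.assert_fitted()
    if registry is None:
        registry = (
            FeatureRegistry.from_config(model.registry_config)
            if model.registry_config
            else FeatureRegistry()
        )
    suite = suite or PropertyPredictorSuite.default()
    vector = full_feature_vector(record, registry, suite)
    return predict_features(model, vector[np.newaxis, :])[0]


def training_config_with_features(config: ModelConfig, features: dict) -> ModelConfig:
    """Convenience: a copy of ``config`` pinned to explicit feature subsets."""
    return dataclasses.replace(config, feature_mode="fixed", fixed_features=features)
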