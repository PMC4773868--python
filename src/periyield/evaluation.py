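"""Assessment machinery: macro-averaged multi-class metrics, regression
metrics, repeated stratified k-fold CV, LOOCV, and leave-one-feature-out
ablation.

Macro definitions (Sokolova-Lapalme style, one-vs-rest per class):

* average accuracy = mean_i (TP_i + TN_i) / n, error rate = 1 - that;
* macro precision / recall = means of the per-class ratios;
* macro F1 = harmonic mean of macro precision and macro recall;
* macro MCC = mean of the per-class binary MCCs.

Per-class ratios with a zero denominator contribute 0 to the macro mean
(affects degenerate folds only).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import (
    ContractViolationError,
    FoldError,
    InsufficientDataError,
    InvalidArgumentError,
    VarianceError,
)

#: Fixed class order used throughout reports and probability vectors.
CLASS_ORDER = ("high", "low", "medium")

CLASSIFICATION_METRICS = (
    "average_accuracy",
    "error_rate",
    "precision",
    "recall",
    "f1",
    "mcc",
)
REGRESSION_METRICS = ("pcc", "mae", "rmse")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest confusion counts for the three classes."""

    classes: tuple[str, ...]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])

    @classmethod
    def from_labels(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        classes: Sequence[str] = CLASS_ORDER,
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ContractViolationError("label vectors differ in length")
        if y_true.size == 0:
            raise InvalidArgumentError("empty label vectors")
        tp, tn, fp, fn = [], [], [], []
        for cls_label in classes:
            is_true = y_true == cls_label
            is_pred = y_pred == cls_label
            tp.append(int(np.sum(is_true & is_pred)))
            tn.append(int(np.sum(~is_true & ~is_pred)))
            fp.append(int(np.sum(~is_true & is_pred)))
            fn.append(int(np.sum(is_true & ~is_pred)))
        return cls(tuple(classes), np.array(tp), np.array(tn), np.array(fp), np.array(fn))


def _ratio(num: float, denom: float) -> float:
    return num / denom if denom != 0 else 0.0


def macro_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Macro-averaged classification metrics from confusion counts."""
    n = counts.n
    if n < 1:
        raise InvalidArgumentError("confusion counts cover no instances")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n_classes = len(counts.classes)

    avg_accuracy = float(np.mean((tp + tn) / n))
    precision = float(np.mean([_ratio(tp[i], tp[i] + fp[i]) for i in range(n_classes)]))
    recall = float(np.mean([_ratio(tp[i], tp[i] + fn[i]) for i in range(n_classes)]))
    f1 = _ratio(2.0 * precision * recall, precision + recall)
    mccs = []
    for i in range(n_classes):
        denom = math.sqrt(
            float(tp[i] + fp[i]) * float(tp[i] + fn[i]) * float(tn[i] + fp[i]) * float(tn[i] + fn[i])
        )
        mccs.append(_ratio(float(tp[i]) * tn[i] - float(fp[i]) * fn[i], denom))
    return {
        "average_accuracy": avg_accuracy,
        "error_rate": 1.0 - avg_accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": float(np.mean(mccs)),
    }


def regression_metrics(predicted: Sequence[float], actual: Sequence[float]) -> tuple[float, float, float]:
    """(PCC, MAE, RMSE) between predicted and actual values."""
    predicted = np.asarray(predicted, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ContractViolationError("predicted/actual must be 1-D and equal length")
    if predicted.size < 2:
        raise InsufficientDataError("PCC needs at least 2 instances")
    err = predicted - actual
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    pc = predicted - predicted.mean()
    ac = actual - actual.mean()
    denom = math.sqrt(float(pc @ pc) * float(ac @ ac))
    if denom == 0.0:
        raise VarianceError("PCC undefined: zero-variance input")
    pcc = float(np.clip((pc @ ac) / denom, -1.0, 1.0))
    return pcc, mae, rmse


# ---------------------------------------------------------------------------
# Cross validation
# ---------------------------------------------------------------------------


def stratified_folds(
    labels: Sequence[str], k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition indices into k class-stratified folds (disjoint, covering)."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < k:
        raise FoldError(f"cannot build {k} folds from {n} instances")
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls_label in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls_label)
        idx = idx[rng.permutation(idx.shape[0])]
        for pos, i in enumerate(idx.tolist()):
            folds[(offset + pos) % k].append(i)
        offset += idx.shape[0]
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


def repeated_kfold_cv(
    dataset,
    config,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    registry=None,
    suite=None,
    matrix: np.ndarray | None = None,
) -> dict:
    """Repeated stratified k-fold CV of the two-stage model.

    Within each repeat every instance is held out exactly once.  Returns
    mean and sample SD of each classification metric over repeats, plus the
    regression metrics of the pooled held-out yield predictions per repeat,
    and the fold assignments for auditability.
    """
    from .two_stage_model import predict_features, train
    from .sequence_features import FeatureRegistry, PropertyPredictorSuite, extract_matrix

    registry = registry or FeatureRegistry()
    suite = suite or PropertyPredictorSuite.default()
    n = len(dataset)
    if n < k:
        raise FoldError(f"cannot build {k} folds from {n} instances")
    if matrix is None:
        matrix = extract_matrix([r for r, _ in dataset.records], registry, suite)
    labels = np.asarray(dataset.labels())
    yields = dataset.yields()
    rng = np.random.default_rng(seed)

    per_repeat: list[dict] = []
    assignments: list[list[np.ndarray]] = []
    for _ in range(repeats):
        folds = stratified_folds(labels, k, rng)
        assignments.append(folds)
        pred_labels = np.empty(n, dtype=object)
        pred_yields = np.empty(n, dtype=np.float64)
        for fold in folds:
            if fold.size == 0:
                continue
            train_idx = np.setdiff1d(np.arange(n), fold)
            model = train(
                dataset.subset(train_idx),
                config,
                registry=registry,
                suite=suite,
                matrix=matrix[train_idx],
            )
            for pos, prediction in zip(
                fold, predict_features(model, matrix[fold])
            ):
                pred_labels[pos] = prediction.label
                pred_yields[pos] = prediction.yield_mg_per_l
        counts = ConfusionCounts.from_labels(labels, pred_labels.astype(str))
        repeat_metrics = macro_metrics(counts)
        try:
            pcc, mae, rmse = regression_metrics(pred_yields, yields)
        except (VarianceError, InsufficientDataError):
            pcc, mae, rmse = float("nan"), float("nan"), float("nan")
        repeat_metrics.update({"pcc": pcc, "mae": mae, "rmse": rmse})
        per_repeat.append(repeat_metrics)

    summary = {}
    for metric in CLASSIFICATION_METRICS + REGRESSION_METRICS:
        values = np.array([r[metric] for r in per_repeat], dtype=np.float64)
        summary[metric] = {
            "mean": float(np.nanmean(values)),
            "sd": float(np.nanstd(values, ddof=1)) if repeats > 1 else 0.0,
        }
    return {"summary": summary, "per_repeat": per_repeat, "fold_assignments": assignments}


def loocv(
    dataset,
    config,
    registry=None,
    suite=None,
    matrix: np.ndarray | None = None,
) -> dict:
    """Leave-one-out CV: n train/test cycles, aggregate metrics at the end."""
    from .two_stage_model import predict_features, train
    from .sequence_features import FeatureRegistry, PropertyPredictorSuite, extract_matrix

    registry = registry or FeatureRegistry()
    suite = suite or PropertyPredictorSuite.default()
    n = len(dataset)
    if n < 3:
        raise InsufficientDataError(f"LOOCV needs n >= 3, got {n}")
    if matrix is None:
        matrix = extract_matrix([r for r, _ in dataset.records], registry, suite)
    labels = np.asarray(dataset.labels())
    yields = dataset.yields()

    predictions = []
    for i in range(n):
        train_idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        model = train(
            dataset.subset(train_idx),
            config,
            registry=registry,
            suite=suite,
            matrix=matrix[train_idx],
        )
        predictions.append(predict_features(model, matrix[i : i + 1])[0])

    pred_labels = np.array([p.label for p in predictions])
    pred_yields = np.array([p.yield_mg_per_l for p in predictions])
    counts = ConfusionCounts.from_labels(labels, pred_labels)
    metrics = macro_metrics(counts)
    try:
        pcc, mae, rmse = regression_metrics(pred_yields, yields)
    except (VarianceError, InsufficientDataError):
        pcc, mae, rmse = float("nan"), float("nan"), float("nan")
    metrics.update({"pcc": pcc, "mae": mae, "rmse": rmse})
    return {"predictions": predictions, "metrics": metrics}


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------


def ablation(
    dataset,
    subset: Sequence[str],
    evaluate: Callable[[object, Sequence[str]], dict[str, float]] | None = None,
    config=None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    registry=None,
    suite=None,
    sort_metric: str = "mcc",
) -> list[tuple[str, dict[str, float]]]:
    """Leave-one-feature-out ablation against the full-subset baseline.

    For each feature, the model is retrained and re-evaluated with that
    feature removed; reported values are percentage changes,
    ``100 * (metric_without - metric_with_all) / metric_with_all``, sorted
    by descending impact on ``sort_metric`` (most negative change first).
    ``evaluate(dataset, feature_names) -> {metric: value}`` defaults to the
    mean classification metrics of repeated k-fold CV with the features
    fixed to ``feature_names``.
    """
    subset = list(subset)
    if len(subset) < 2:
        raise InvalidArgumentError("ablation needs a subset of at least 2 features")

    if evaluate is None:
        if config is None:
            raise InvalidArgumentError("ablation needs either an evaluate fn or a config")
        from .sequence_features import FeatureRegistry, PropertyPredictorSuite, extract_matrix

        registry = registry or FeatureRegistry()
        suite = suite or PropertyPredictorSuite.default()
        matrix = extract_matrix([r for r, _ in dataset.records], registry, suite)

        def evaluate(ds, feature_names):  # noqa: F811 - documented default
            cfg = dataclasses.replace(
                config,
                feature_mode="fixed",
                fixed_features={t: list(feature_names) for t in _ALL_TASKS},
            )
            report = repeated_kfold_cv(
                ds, cfg, k=k, repeats=repeats, seed=seed,
                registry=registry, suite=suite, matrix=matrix,
            )
            return {m: report["summary"][m]["mean"] for m in CLASSIFICATION_METRICS}

    baseline = evaluate(dataset, subset)
    results = []
    for feature in subset:
        reduced = [f for f in subset if f != feature]
        ablated = evaluate(dataset, reduced)
        changes = {}
        for metric, base_value in baseline.items():
            if base_value == 0:
                changes[metric] = float("nan")
            else:
                changes[metric] = 100.0 * (ablated[metric] - base_value) / base_value
        results.append((feature, changes))

    key_metric = sort_metric if sort_metric in baseline else next(iter(baseline))
    results.sort(key=lambda item: item[1].get(key_metric, 0.0))
    return results


_ALL_TASKS = ("classification", "reg_high", "reg_medium", "reg_low")


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def write_cv_report(path, report: dict) -> None:
    """Tab-separated summary table (metric, mean, sd)."""
    with open(path, "w") as handle:
        handle.write("metric\tmean\tsd\n")
        for metric, stats in report["summary"].items():
            handle.write(f"{metric}\t{stats['mean']:.6g}\t{stats['sd']:.6g}\n")


def write_ablation_report(path, results: list[tuple[str, dict[str, float]]]) -> None:
    """Tab-separated ablation table (feature, pct change per metric)."""
    if not results:
        raise InvalidArgumentError("empty ablation results")
    metrics = list(results[0][1])
    with open(path, "w") as handle:
        handle.write("feature_removed\t" + "\t".join(metrics) + "\n")
        for feature, changes in results:
            row = "\t".join(f"{changes[m]:.4g}" for m in metrics)
            handle.write(f"{feature}\t{row}\n")
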