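"""Labelled sequence dataset generator with planted feature-yield signal.

Random sequences are drawn over the 20-letter alphabet; a latent log10
yield is an affine function of a small set of planted registry features
(z-scored within the sample) plus Gaussian noise.  The latent score is then
affinely calibrated so that the realized class proportions match the
configured targets: the low/high cut points are placed at the appropriate
order statistics and mapped onto the printed class thresholds (0.5 and
100 mg/l).  Yields are exponentiated to mg/l, so they are positive and span
several orders of magnitude, and the generator's internal labels coincide
with ``yield_to_class`` of the emitted yields by construction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, SimulationInfeasibleError
from .io_cli import LabelledDataset, split_dataset
from .sequence_features import (
    ALPHABET,
    FeatureRegistry,
    PropertyPredictorSuite,
    SequenceRecord,
    extract_matrix,
)
from .two_stage_model import (
    HIGH_THRESHOLD,
    LOW_THRESHOLD,
    ModelConfig,
    predict_features,
    regress_raw,
    train,
)

#: Default class proportions, matching the curated 98-instance composition.
DEFAULT_PROPORTIONS = (16 / 98, 58 / 98, 24 / 98)  # high, medium, low


@dataclass(frozen=True)
class SimulationConfig:
    n: int = 98
    length_range: tuple[int, int] = (50, 600)
    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS  # high, medium, low
    planted: tuple[tuple[str, float], ...] = (("dp_QD", 1.0),)
    noise_sd: float = 0.3  # log10 mg/l
    seed: int = 0
    planted_boost: int = 0  # max individual inserted copies per planted dipeptide
    planted_boost_shared: int = 0  # max additional copies shared across planted dipeptides

    def __post_init__(self):
        if self.n < 9:
            raise InvalidArgumentError(f"n must be >= 9 (>= 3 per class), got {self.n}")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise InvalidArgumentError(f"invalid length range {self.length_range}")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise InvalidArgumentError("class proportions must sum to 1")
        if any(p <= 0 for p in self.proportions):
            raise InvalidArgumentError("class proportions must all be positive")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")


def _random_sequences(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n)
    sequences = []
    boosted = [
        name[3:]
        for name, _ in config.planted
        if name.startswith("dp_") and config.planted_boost > 0
    ]
    for length in lengths:
        residues = list(rng.integers(0, 20, size=int(length)))
        seq = [ALPHABET[i] for i in residues]
        # a shared copy count correlates the planted dipeptide occurrences,
        # boosting each feature's marginal correlation with the latent yield
        shared = (
            int(rng.integers(0, config.planted_boost_shared + 1))
            if boosted and config.planted_boost_shared > 0
            else 0
        )
        for pair in boosted:
            copies = shared + int(rng.integers(0, config.planted_boost + 1))
            for _ in range(copies):
                pos = int(rng.integers(0, len(seq) - 1))
                seq[pos], seq[pos + 1] = pair[0], pair[1]
        sequences.append("".join(seq))
    return sequences


def _zscore(column: np.ndarray) -> np.ndarray:
    sd = column.std(ddof=1)
    if sd == 0:
        return np.zeros_like(column)
    return (column - column.mean()) / sd


def simulate_dataset(
    config: SimulationConfig,
    registry: FeatureRegistry | None = None,
    suite: PropertyPredictorSuite | None = None,
) -> LabelledDataset:
    """Generate a labelled dataset whose log10 yield follows planted features."""
    registry = registry or FeatureRegistry()
    suite = suite or PropertyPredictorSuite.default()
    for name, _ in config.planted:
        registry.index_of(name)  # raises for unknown planted features

    rng = np.random.default_rng(config.seed)
    sequences = _random_sequences(config, rng)
    records = [SequenceRecord(f"syn{i:04d}", seq) for i, seq in enumerate(sequences)]
    matrix = extract_matrix(records, registry, suite)

    latent = rng.normal(0.0, config.noise_sd, size=config.n)
    for name, effect in config.planted:
        latent = latent + effect * _zscore(matrix[:, registry.index_of(name)])

    p_high, _, p_low = config.proportions
    n_low = max(1, int(round(p_low * config.n)))
    n_high = max(1, int(round(p_high * config.n)))
    if n_low + n_high >= config.n:
        raise SimulationInfeasibleError("proportions leave no medium instances")

    order = np.sort(latent)
    cut_low = order[n_low - 1]
    cut_high = 0.5 * (order[config.n - n_high - 1] + order[config.n - n_high])
    if not cut_high > cut_low:
        raise SimulationInfeasibleError(
            "latent yield signal cannot span the class thresholds "
            "(planted effects too weak or degenerate)"
        )
    slope = (math.log10(HIGH_THRESHOLD) - math.log10(LOW_THRESHOLD)) / (cut_high - cut_low)
    intercept = math.log10(LOW_THRESHOLD) - slope * cut_low
    yields = 10.0 ** (intercept + slope * latent)

    dataset = LabelledDataset(
        list(zip(records, yields.tolist())),
        provenance={
            "generator": "simulate_dataset",
            "seed": config.seed,
            "planted": list(config.planted),
            "calibration": {"slope": slope, "intercept": intercept},
        },
    )
    return dataset


def planted_recovery_check(
    config: SimulationConfig,
    pipeline: ModelConfig | None = None,
    registry: FeatureRegistry | None = None,
    suite: PropertyPredictorSuite | None = None,
    test_fraction: float = 0.5,
) -> dict:
    """Run selection + two-stage training on simulated data; report recovery.

    Feature selection runs on the standardized training matrix against the
    continuous log10 yield; the two-stage model is then trained with the
    selected subset and scored on the held-out split (macro average
    accuracy, and per-class PCC of each class regressor evaluated on the
    true-class test instances).
    """
    from .feature_selection import forward_select
    from .evaluation import CLASS_ORDER, ConfusionCounts, macro_metrics, regression_metrics
    from .preprocessing import apply_standardizer, fit_standardizer

    pipeline = pipeline or ModelConfig()
    registry = registry or FeatureRegistry()
    suite = suite or PropertyPredictorSuite.default()

    dataset = simulate_dataset(config, registry, suite)
    train_set, test_set = split_dataset(dataset, test_fraction, seed=config.seed)
    matrix_train = extract_matrix([r for r, _ in train_set.records], registry, suite)
    matrix_test = extract_matrix([r for r, _ in test_set.records], registry, suite)

    std = fit_standardizer(matrix_train)
    selected_idx = forward_select(
        apply_standardizer(std, matrix_train),
        np.log10(train_set.yields()),
        max_subset_size=pipeline.max_subset_size,
        tie_tol=pipeline.tie_tol,
        classification=False,
    )
    names = registry.all_names
    selected = [names[i] for i in selected_idx]
    planted_names = [name for name, _ in config.planted]
    recovered = {name: name in selected for name in planted_names}

    fixed = {t: selected for t in ("classification", "reg_high", "reg_medium", "reg_low")}
    model_config = dataclasses.replace(
        pipeline, feature_mode="fixed", fixed_features=fixed
    )
    model = train(train_set, model_config, registry=registry, suite=suite, matrix=matrix_train)

    predictions = predict_features(model, matrix_test)
    true_labels = np.asarray(test_set.labels())
    pred_labels = np.array([p.label for p in predictions])
    counts = ConfusionCounts.from_labels(true_labels, pred_labels)
    accuracy = macro_metrics(counts)["average_accuracy"]

    class_pcc: dict[str, float] = {}
    test_yields = test_set.yields()
    for cls_label in CLASS_ORDER:
        rows = np.flatnonzero(true_labels == cls_label)
        if rows.size < 2:
            class_pcc[cls_label] = float("nan")
            continue
        raw = regress_raw(model, cls_label, matrix_test[rows])
        try:
            pcc, _, _ = regression_metrics(raw, test_yields[rows])
        except Exception:
            pcc = float("nan")
        class_pcc[cls_label] = pcc

    return {
        "selected": selected,
        "planted_recovered": recovered,
        "all_recovered": all(recovered.values()),
        "macro_accuracy": accuracy,
        "class_pcc": class_pcc,
        "n_train": len(train_set),
        "n_test": len(test_set),
    }
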