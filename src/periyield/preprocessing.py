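"""Z-score standardization fitted on training data and replayed on new data.

Means use the column average; standard deviations use the sample (n-1)
denominator.  Constant columns (sigma = 0) standardize to 0 rather than
dividing by zero.  The model is fitted on training rows only and frozen, so
prediction-time data reuses the training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolationError, InsufficientDataError


@dataclass(frozen=True)
class StandardizationModel:
    """Per-feature training means and sample standard deviations."""

    mean: np.ndarray
    std: np.ndarray
    feature_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=np.float64)
        std = np.asarray(self.std, dtype=np.float64)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)
        if mean.shape != std.shape or mean.ndim != 1:
            raise ContractViolationError("mean/std must be 1-D arrays of equal length")
        if np.any(std < 0):
            raise ContractViolationError("negative standard deviation in model")

    def __len__(self) -> int:
        return self.mean.shape[0]

    def subset(self, indices) -> "StandardizationModel":
        """Restriction of the model to the given feature indices."""
        names = (
            tuple(self.feature_names[i] for i in indices)
            if self.feature_names is not None
            else None
        )
        return StandardizationModel(self.mean[indices], self.std[indices], names)


def fit_standardizer(
    matrix: np.ndarray, feature_names: tuple[str, ...] | None = None
) -> StandardizationModel:
    """Fit per-column mean and sample (n-1) standard deviation."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ContractViolationError("fit_standardizer expects an n x p matrix")
    if matrix.shape[0] < 2:
        raise InsufficientDataError(
            f"standardization needs at least 2 rows, got {matrix.shape[0]}"
        )
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0, ddof=1)
    return StandardizationModel(mean, std, feature_names)


def apply_standardizer(model: StandardizationModel, values: np.ndarray) -> np.ndarray:
    """(x - mu) / sigma per feature; constant features (sigma = 0) map to 0."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[-1] != len(model):
        raise ContractViolationError(
            f"feature count {values.shape[-1]} does not match model length {len(model)}"
        )
    safe_std = np.where(model.std == 0.0, 1.0, model.std)
    out = (values - model.mean) / safe_std
    return np.where(model.std == 0.0, 0.0, out)
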