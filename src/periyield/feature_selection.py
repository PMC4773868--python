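"""Correlation-based feature selection (CFS) with forward subset search.

The merit of a feature subset of size k is

    merit = (k * mean|r_cf|) / sqrt(k + k * (k - 1) * mean|r_ff|)

where ``r_cf`` are feature-target correlations and ``r_ff`` feature-feature
correlations.  Subsets that correlate strongly with the target but weakly
with each other score highest.  Forward search greedily adds the feature
that maximizes merit until no addition improves it beyond ``tie_tol`` or
the size cap is reached; ties break toward the lowest feature index, so
selection is deterministic.

Correlations are Pearson on the (standardized) feature columns.  For a
three-class target, each feature's target correlation is the maximum over
classes of |Pearson(feature, class indicator)| — a continuous CFS variant
that avoids a discretization policy.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError, NoSignalError

#: Natural ordering of expression classes, used for the ordinal encoding.
CLASS_ORDINAL = {"low": 0.0, "medium": 1.0, "high": 2.0}


def _guarded_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0.0 when either input has zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _column_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson| of every column of X against y, with zero-variance guard."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    x_norm = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    y_norm = np.sqrt(yc @ yc)
    denom = x_norm * y_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / denom
    r[denom == 0.0] = 0.0
    return np.clip(np.abs(r), 0.0, 1.0)


def class_correlation(
    values: np.ndarray, labels: Sequence, method: str = "ordinal"
) -> float:
    """Correlation between one feature and a 3-class label vector.

    ``method='ordinal'`` (default) encodes low < medium < high (or, for
    arbitrary labels, their sorted order) as 0, 1, 2 and returns the signed
    Pearson correlation.  ``method='indicator'`` returns the maximum over
    classes of |Pearson(feature, one-hot indicator)| — the variant the
    forward search uses as ``r_cf`` for classification targets.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    distinct = sorted(set(labels.tolist()), key=lambda c: CLASS_ORDINAL.get(c, c))
    if len(distinct) < 2:
        raise NoSignalError("labels contain a single class; no class signal")
    if method == "ordinal":
        codes = np.array([distinct.index(c) for c in labels.tolist()], dtype=np.float64)
        return _guarded_pearson(values, codes)
    if method == "indicator":
        return max(
            abs(_guarded_pearson(values, (labels == cls).astype(np.float64)))
            for cls in distinct
        )
    raise InvalidArgumentError(f"unknown method {method!r}")


class CorrelationCache:
    """Feature-target correlations plus lazily computed feature-feature ones."""

    def __init__(self, X: np.ndarray, r_cf: np.ndarray):
        self.X = np.asarray(X, dtype=np.float64)
        self.r_cf = np.asarray(r_cf, dtype=np.float64)
        if self.r_cf.shape[0] != self.X.shape[1]:
            raise InvalidArgumentError("r_cf length must match feature count")
        self._ff_rows: dict[int, np.ndarray] = {}

    @classmethod
    def from_target(cls, X: np.ndarray, y: np.ndarray, classification: bool = False):
        X = np.asarray(X, dtype=np.float64)
        if classification:
            labels = np.asarray(y)
            classes = sorted(set(labels.tolist()))
            r = np.zeros(X.shape[1])
            for cls_label in classes:
                indicator = (labels == cls_label).astype(np.float64)
                r = np.maximum(r, _column_correlations(X, indicator))
            return cls(X, r)
        return cls(X, _column_correlations(X, np.asarray(y, dtype=np.float64)))

    @classmethod
    def from_correlations(cls, r_cf: np.ndarray, r_ff: np.ndarray) -> "CorrelationCache":
        """Build a cache directly from explicit correlation tables."""
        r_cf = np.asarray(r_cf, dtype=np.float64)
        cache = cls.__new__(cls)
        cache.X = None
        cache.r_cf = r_cf
        r_ff = np.asarray(r_ff, dtype=np.float64)
        cache._ff_rows = {j: np.abs(r_ff[j]) for j in range(r_ff.shape[0])}
        return cache

    def ff_row(self, j: int) -> np.ndarray:
        """|r_ff| of every feature against feature j."""
        if j not in self._ff_rows:
            self._ff_rows[j] = _column_correlations(self.X, self.X[:, j])
        return self._ff_rows[j]

    def ff(self, i: int, j: int) -> float:
        return float(self.ff_row(j)[i])


def cfs_merit(subset: Sequence[int], cache: CorrelationCache) -> float:
    """CFS merit of a subset of feature indices."""
    subset = list(subset)
    if not subset:
        raise InvalidArgumentError("cfs_merit requires a non-empty subset")
    k = len(subset)
    mean_rcf = float(np.mean(np.abs(cache.r_cf[subset])))
    if k == 1:
        return mean_rcf
    pair_sum = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            pair_sum += cache.ff(subset[a], subset[b])
    mean_rff = pair_sum / (k * (k - 1) / 2)
    return (k * mean_rcf) / np.sqrt(k + k * (k - 1) * mean_rff)


def forward_select(
    X: np.ndarray,
    y: Sequence,
    max_subset_size: int = 20,
    tie_tol: float = 1e-6,
    classification: bool | None = None,
) -> list[int]:
    """Greedy CFS subset growth; returns selected indices in selection order.

    ``y`` may be numeric targets (regression) or class labels; if
    ``classification`` is None it is inferred from the dtype of ``y``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InvalidArgumentError("X must be an n x p matrix with p >= 1")
    if X.shape[0] < 3:
        raise InvalidArgumentError("forward_select needs n >= 3 rows")
    y_arr = np.asarray(y)
    if classification is None:
        classification = not np.issubdtype(y_arr.dtype, np.number)
    if len(set(np.asarray(y_arr).tolist())) < 2:
        raise NoSignalError("target is degenerate (all values identical)")

    cache = CorrelationCache.from_target(X, y_arr, classification=classification)
    p = X.shape[1]
    selected: list[int] = []
    sum_rcf = 0.0  # sum of |r_cf| over selected
    pair_sum_sel = 0.0  # sum of |r_ff| over selected pairs
    ff_sum = np.zeros(p)  # per candidate: sum of |r_ff| against selected
    best_merit = 0.0

    while len(selected) < max_subset_size:
        k = len(selected) + 1
        mean_rcf = (sum_rcf + cache.r_cf) / k
        if k == 1:
            merit = mean_rcf
        else:
            mean_rff = (pair_sum_sel + ff_sum) / (k * (k - 1) / 2)
            merit = (k * mean_rcf) / np.sqrt(k + k * (k - 1) * mean_rff)
        merit = np.asarray(merit, dtype=np.float64)
        merit[selected] = -np.inf
        top = float(merit.max())
        if not np.isfinite(top) or top <= best_merit + tie_tol:
            break
        # lowest index within tie_tol of the maximum wins
        j = int(np.flatnonzero(merit >= top - tie_tol)[0])
        selected.append(j)
        best_merit = float(merit[j])
        sum_rcf += float(cache.r_cf[j])
        pair_sum_sel += float(ff_sum[j])
        ff_sum = ff_sum + cache.ff_row(j)
    return selected
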