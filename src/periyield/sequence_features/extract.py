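"""Feature extraction operations.

All functions are pure: the same sequence, registry and suite always give
bit-identical output.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from ..errors import ContractViolationError, InvalidArgumentError
from .properties import PropertyPredictorSuite
from .records import ResidueGroup, SequenceRecord
from .registry import FeatureRegistry
from .scales import (
    ALPHABET,
    PKA_CTERM,
    PKA_NEGATIVE,
    PKA_NTERM,
    PKA_POSITIVE,
)


def aa_composition(record: SequenceRecord) -> dict[str, float]:
    """Occurrence frequency of each of the 20 residues (count / length)."""
    counts = np.bincount(record.encoded(), minlength=20)
    freqs = counts / len(record)
    return {aa: float(freqs[i]) for i, aa in enumerate(ALPHABET)}


def _max_run_bool(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    edges = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max())


def max_consecutive_run(record: SequenceRecord, group: ResidueGroup) -> int:
    """Length of the longest contiguous stretch of group members; 0 if absent.

    For a single-residue group this is the per-residue maximum run of
    identical letters.
    """
    member_mask = group.mask()[record.encoded()]
    return _max_run_bool(member_mask)


def dipeptide_occurrences(record: SequenceRecord) -> np.ndarray:
    """Overlapping counts of each ordered residue pair (400 integers).

    Counts sum to ``len(sequence) - 1``.  Registry order is first residue
    major, both alphabetical.
    """
    enc = record.encoded()
    pair_codes = enc[:-1] * 20 + enc[1:]
    return np.bincount(pair_codes, minlength=400).astype(np.int64)


def net_charge(record: SequenceRecord, ph: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH (EMBOSS pKa set)."""
    seq = record.sequence
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    for residue, pka in PKA_POSITIVE.items():
        n = seq.count(residue)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka))
    for residue, pka in PKA_NEGATIVE.items():
        n = seq.count(residue)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(record: SequenceRecord) -> float:
    """pH of zero net charge, solved by bisection to <1e-3 pH units."""
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        if net_charge(record, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def abs_charge_per_residue(record: SequenceRecord) -> float:
    """|(nK + nR + nH) - (nD + nE)| / length.

    Histidine counts as positive, consistent with the basic/positively
    charged residue group {H, K, R}.
    """
    seq = record.sequence
    positive = seq.count("K") + seq.count("R") + seq.count("H")
    negative = seq.count("D") + seq.count("E")
    return abs(positive - negative) / len(seq)


def physchem_scalars(
    record: SequenceRecord, registry: FeatureRegistry | None = None
) -> dict:
    """Length, group frequencies, absolute charge per residue and pI."""
    registry = registry or FeatureRegistry()
    counts = np.bincount(record.encoded(), minlength=20)
    length = len(record)
    group_freq = {
        g.name: float(counts[g.mask()].sum() / length) for g in registry.groups
    }
    return {
        "length": float(length),
        "group_frequencies": group_freq,
        "abs_charge_per_residue": abs_charge_per_residue(record),
        "isoelectric_point": isoelectric_point(record),
    }


def predicted_properties(
    record: SequenceRecord, suite: PropertyPredictorSuite
) -> dict[str, float]:
    """One finite value per registered property contract."""
    return suite.compute(record.sequence)


def base_feature_vector(
    record: SequenceRecord,
    registry: FeatureRegistry | None = None,
    suite: PropertyPredictorSuite | None = None,
) -> np.ndarray:
    """The 122 base features, in registry order."""
    registry = registry or FeatureRegistry()
    suite = suite or PropertyPredictorSuite.default()
    enc = record.encoded()
    counts = np.bincount(enc, minlength=20)
    length = len(record)
    props: Mapping[str, float] | None = None

    values = np.empty(registry.n_base, dtype=np.float64)
    for pos, fdef in enumerate(registry.base_defs):
        if fdef.kind == "length":
            values[pos] = float(length)
        elif fdef.kind == "aa_freq":
            values[pos] = counts[ALPHABET.index(fdef.key)] / length
        elif fdef.kind == "aa_run":
            values[pos] = _max_run_bool(enc == ALPHABET.index(fdef.key))
        elif fdef.kind == "group_freq":
            group = registry.group(fdef.key)
            values[pos] = counts[group.mask()].sum() / length
        elif fdef.kind == "group_run":
            group = registry.group(fdef.key)
            values[pos] = _max_run_bool(group.mask()[enc])
        elif fdef.kind == "abs_charge":
            values[pos] = abs_charge_per_residue(record)
        elif fdef.kind == "pi":
            values[pos] = isoelectric_point(record)
        elif fdef.kind == "property":
            if props is None:
                props = predicted_properties(record, suite)
            values[pos] = props[fdef.key]
        else:  # pragma: no cover - registry construction forbids this
            raise InvalidArgumentError(f"unknown feature kind {fdef.kind!r}")
    return values


def interactive_features(base: np.ndarray) -> np.ndarray:
    """Products of every unordered base-feature pair (i < j), 7,381 values."""
    base = np.asarray(base, dtype=np.float64)
    if base.ndim != 1 or base.shape[0] != 122:
        raise ContractViolationError(
            f"interactive_features expects a 122-vector, got shape {base.shape}"
        )
    iu, ju = np.triu_indices(base.shape[0], k=1)
    return base[iu] * base[ju]


def full_feature_vector(
    record: SequenceRecord,
    registry: FeatureRegistry | None = None,
    suite: PropertyPredictorSuite | None = None,
) -> np.ndarray:
    """Concatenated base (122) + interactive (7,381) + dipeptide (400)."""
    registry = registry or FeatureRegistry()
    base = base_feature_vector(record, registry, suite)
    dipeptides = dipeptide_occurrences(record).astype(np.float64)
    return np.concatenate([base, interactive_features(base), dipeptides])


def extract_matrix(
    records: Iterable[SequenceRecord],
    registry: FeatureRegistry | None = None,
    suite: PropertyPredictorSuite | None = None,
) -> np.ndarray:
    """Stack full feature vectors for many records into an n x 7,903 matrix."""
    registry = registry or FeatureRegistry()
    suite = suite or PropertyPredictorSuite.default()
    rows = [full_feature_vector(rec, registry, suite) for rec in records]
    if not rows:
        raise InvalidArgumentError("extract_matrix called with no records")
    return np.vstack(rows)
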