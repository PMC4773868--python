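"""Pluggable predicted-property suite with deterministic defaults.

The original workflow relied on external predictors (folding rate,
transmembrane segments, solubility, disorder).  Those tools are replaced
here by documented, deterministic sequence-derived stand-ins so the whole
pipeline runs offline; every predictor is a ``sequence -> finite float``
contract and can be swapped for the real tool's output.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping

import numpy as np

from ..errors import PropertyUnavailableError
from .scales import (
    CHOU_FASMAN_COIL,
    CHOU_FASMAN_HELIX,
    CHOU_FASMAN_SHEET,
    CONTACT_NUMBER,
    DISORDER_PROMOTING,
    EXPOSED_RESIDUES,
    KYTE_DOOLITTLE,
)

#: Registry order of the predicted/derived properties (11 features).
PROPERTY_NAMES: tuple[str, ...] = (
    "logPFR",
    "nlogPFR",
    "solubility",
    "unfoldability",
    "disorder_count",
    "transmembrane",
    "exposed_fraction",
    "contact_number",
    "helix_propensity",
    "sheet_propensity",
    "coil_propensity",
)

LN10 = math.log(10.0)

_TM_WINDOW = 19
_TM_THRESHOLD = 1.6


def _mean_scale(sequence: str, scale: Mapping[str, float]) -> float:
    return float(sum(scale[c] for c in sequence) / len(sequence))


def _scaled_hydropathy(sequence: str) -> float:
    # Kyte-Doolittle rescaled to [0, 1].
    return (_mean_scale(sequence, KYTE_DOOLITTLE) + 4.5) / 9.0


def default_log_folding_rate(sequence: str) -> float:
    """Chain-length power law with a hydropathy adjustment (log10 scale).

    Stand-in for an external folding-rate predictor: rate decreases with
    chain length and is modulated by mean hydropathy.
    """
    length = len(sequence)
    return 9.0 - 2.6 * math.log10(length) + 1.5 * (_scaled_hydropathy(sequence) - 0.5)


def default_solubility(sequence: str) -> float:
    """Mean per-residue solubility propensity, (4.5 - KD) / 9 in [0, 1]."""
    return float(
        sum((4.5 - KYTE_DOOLITTLE[c]) / 9.0 for c in sequence) / len(sequence)
    )


def default_unfoldability(sequence: str) -> float:
    """Negated fold-index: 1.151 + |<q>| - 2.785 * <H>.

    ``<H>`` is mean hydropathy scaled to [0, 1] and ``<q>`` is mean net
    charge per residue (K, R positive; D, E negative).  Larger values mean
    more predicted disorder.
    """
    q = (
        sequence.count("K") + sequence.count("R")
        - sequence.count("D") - sequence.count("E")
    ) / len(sequence)
    return 1.151 + abs(q) - 2.785 * _scaled_hydropathy(sequence)


def default_disorder_count(sequence: str) -> float:
    """Count of disorder-promoting residues (A, R, S, Q, E, G, K, P)."""
    return float(sum(1 for c in sequence if c in DISORDER_PROMOTING))


def default_transmembrane(sequence: str) -> float:
    """Number of hydrophobic segments of window-averaged KD > 1.6.

    Sliding 19-residue windows; contiguous above-threshold windows are
    merged into one segment.  Sequences shorter than the window give 0.
    """
    if len(sequence) < _TM_WINDOW:
        return 0.0
    kd = np.array([KYTE_DOOLITTLE[c] for c in sequence])
    means = np.convolve(kd, np.full(_TM_WINDOW, 1.0 / _TM_WINDOW), mode="valid")
    above = means > _TM_THRESHOLD
    if not above.any():
        return 0.0
    edges = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    return float(np.count_nonzero(edges == 1))


def default_exposed_fraction(sequence: str) -> float:
    return float(sum(1 for c in sequence if c in EXPOSED_RESIDUES) / len(sequence))


def default_contact_number(sequence: str) -> float:
    return _mean_scale(sequence, CONTACT_NUMBER)


def default_helix_propensity(sequence: str) -> float:
    return _mean_scale(sequence, CHOU_FASMAN_HELIX)


def default_sheet_propensity(sequence: str) -> float:
    return _mean_scale(sequence, CHOU_FASMAN_SHEET)


def default_coil_propensity(sequence: str) -> float:
    return _mean_scale(sequence, CHOU_FASMAN_COIL)


class PropertyPredictorSuite:
    """Maps property names to deterministic ``sequence -> float`` callables.

    ``nlogPFR`` (natural-log folding rate) is derived as
    ``logPFR * ln(10)`` whenever the suite does not define it explicitly,
    so the base-change identity holds by construction for the defaults.
    """

    def __init__(self, predictors: Mapping[str, Callable[[str], float]]):
        self._predictors = dict(predictors)

    @classmethod
    def default(cls) -> "PropertyPredictorSuite":
        return cls(
            {
                "logPFR": default_log_folding_rate,
                "solubility": default_solubility,
                "unfoldability": default_unfoldability,
                "disorder_count": default_disorder_count,
                "transmembrane": default_transmembrane,
                "exposed_fraction": default_exposed_fraction,
                "contact_number": default_contact_number,
                "helix_propensity": default_helix_propensity,
                "sheet_propensity": default_sheet_propensity,
                "coil_propensity": default_coil_propensity,
            }
        )

    @classmethod
    def constant(cls, value: float = 1.0) -> "PropertyPredictorSuite":
        """Stub suite mapping every property (nlogPFR included) to ``value``."""
        return cls({name: (lambda seq, v=value: v) for name in PROPERTY_NAMES})

    def compute(self, sequence: str) -> dict[str, float]:
        """Evaluate every registered property; one finite value per name."""
        out: dict[str, float] = {}
        for name in PROPERTY_NAMES:
            fn = self._predictors.get(name)
            if fn is None:
                if name == "nlogPFR" and "logPFR" in out:
                    out[name] = out["logPFR"] * LN10
                    continue
                raise PropertyUnavailableError(name, f"no predictor registered for {name!r}")
            try:
                value = float(fn(sequence))
            except PropertyUnavailableError:
                raise
            except Exception as exc:  # predictor failure -> named error
                raise PropertyUnavailableError(name, f"{name!r} predictor raised: {exc}") from exc
            if not math.isfinite(value):
                raise PropertyUnavailableError(name, f"{name!r} returned non-finite {value!r}")
            out[name] = value
        return out
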