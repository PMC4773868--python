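"""Exception hierarchy for the periyield package.

Every error raised on a documented failure path derives from
:class:`PeriyieldError`, so callers can catch the package's errors with a
single except clause while still distinguishing the specific condition.
"""


class PeriyieldError(Exception):
    """Base class for all periyield errors."""


class InvalidSequenceError(PeriyieldError, ValueError):
    """A sequence failed validation (illegal residue letter, too short)."""


class InvalidArgumentError(PeriyieldError, ValueError):
    """An argument violated a documented precondition."""


class ContractViolationError(PeriyieldError, ValueError):
    """An internal interface contract was violated (e.g. length mismatch)."""


class PropertyUnavailableError(PeriyieldError, RuntimeError):
    """A predicted-property contract failed; carries the property name."""

    def __init__(self, property_name: str, message: str | None = None):
        self.property_name = property_name
        super().__init__(message or f"property predictor failed: {property_name!r}")


class InsufficientDataError(PeriyieldError, ValueError):
    """Too few instances for the requested operation."""


class NoSignalError(PeriyieldError, ValueError):
    """Target is degenerate (constant labels / zero variance)."""


class UncoveredClassError(PeriyieldError, ValueError):
    """Training data misses one or more expression classes."""

    def __init__(self, missing, message: str | None = None):
        self.missing = tuple(missing)
        super().__init__(
            message or f"training data lacks instances for classes: {', '.join(self.missing)}"
        )


class ModelStateError(PeriyieldError, RuntimeError):
    """Model was used before being trained, or is internally inconsistent."""


class FoldError(PeriyieldError, ValueError):
    """Cross-validation fold structure cannot be built (n < k, ...)."""


class ParseError(PeriyieldError, ValueError):
    """Input file could not be parsed; message names the offending record."""


class StratificationError(PeriyieldError, ValueError):
    """A class is too small to stratify the requested split."""


class ModelLoadError(PeriyieldError, RuntimeError):
    """A persisted model bundle could not be loaded."""


class ModelVersionError(ModelLoadError):
    """A persisted model bundle has an unsupported format version."""


class SimulationInfeasibleError(PeriyieldError, ValueError):
    """Simulation config cannot realize the requested class structure."""


class VarianceError(PeriyieldError, ValueError):
    """A correlation was requested on zero-variance input."""
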