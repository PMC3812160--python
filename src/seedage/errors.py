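"""Exception hierarchy shared across the pipeline stages."""


class SeedageError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SeedageError, ValueError):
    """A parameter violates its domain (nonpositive hydration, K > n, ...)."""


class InvalidInputError(SeedageError, ValueError):
    """An input record or collection violates a precondition."""


class UndefinedPotentialError(SeedageError, ValueError):
    """Half-cell potential requested for a zero/negative concentration."""


class NoAmplificationError(SeedageError, ValueError):
    """A qPCR fluorescence curve shows no rise above baseline noise."""


class FitError(SeedageError, RuntimeError):
    """A nonlinear fit failed to converge (distinct from no-amplification)."""


class InsufficientDataError(SeedageError, ValueError):
    """Too few observations for the requested estimate."""


class DegenerateArrayError(SeedageError, ValueError):
    """An array is too small/degenerate to normalize."""


class DegenerateScaleError(SeedageError, ValueError):
    """A scale estimator evaluated to zero."""


class SeparationError(SeedageError, RuntimeError):
    """Probit fit is degenerate (complete separation or constant dose)."""


class UnboundedZoneError(SeedageError, ValueError):
    """Dose-at-quantile undefined because the slope is (numerically) zero."""


class SchemaError(SeedageError, ValueError):
    """A tabular input violates its declared schema (exit code 2)."""


class StageError(SeedageError, RuntimeError):
    """A pipeline stage failed (exit code 3); carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
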