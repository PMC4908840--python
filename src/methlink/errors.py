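"""Exception hierarchy for the methlink pipeline.

All exceptions derive from :class:`MethlinkError` so callers can catch
pipeline failures with a single except clause while still distinguishing
configuration problems from data problems.
"""


class MethlinkError(Exception):
    """Base class for all methlink errors."""


class ConfigurationError(MethlinkError):
    """A configuration value, dialect mapping or simulation parameter is invalid."""


class InputDataError(MethlinkError):
    """An input file or matrix is empty, malformed or out of range."""


class StagingError(InputDataError):
    """A fibrosis-stage or steatosis-grade label is not recognised."""


class GeneLookupError(MethlinkError):
    """A gene symbol has no coordinate record."""


class CohortCompositionError(InputDataError):
    """A cohort lacks a diagnosis class required by the requested scan."""


class SingularDesignError(MethlinkError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class InsufficientDataError(MethlinkError):
    """Too few observations remain for the requested model."""


class InsufficientVariationError(MethlinkError):
    """A predictor is constant, leaving nothing to regress on."""


class AggregationError(MethlinkError):
    """A site set to aggregate over is empty or absent from the matrix."""


class CorrelationError(MethlinkError):
    """A correlation input has zero variance or too few observations."""


class FitConvergenceError(MethlinkError):
    """A robust fit did not converge within the iteration cap."""

    def __init__(self, message, iterations=None, maxiter=None):
        super().__init__(message)
        self.iterations = iterations
        self.maxiter = maxiter


class PipelineStageError(MethlinkError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
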