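"""Exception hierarchy shared across castsim modules."""


class CastError(Exception):
    """Base class for all castsim errors."""


class InvalidArgumentError(CastError, ValueError):
    """An argument violates a documented precondition."""


class ResourceExhaustedError(CastError, RuntimeError):
    """A problem-bank cell (or similar finite resource) is empty."""


class UndefinedMeasureError(CastError, ValueError):
    """A derived measure is undefined for the given trial log."""


class SchemaError(CastError, ValueError):
    """A tabular artifact is missing a mandatory column or is malformed."""


class CalibrationError(CastError, RuntimeError):
    """An effect-size target cannot be reached by the cost mapping."""


class RankDeficiencyError(CastError, ValueError):
    """A regression design matrix is rank deficient.

    ``columns`` names the offending (collinear or constant-zero) columns.
    """

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"rank-deficient design matrix; collinear columns: {self.columns}")


class SeparationError(CastError, RuntimeError):
    """A binomial regression is degenerate (complete separation / boundary)."""
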