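"""Exception hierarchy shared by all xylograft modules."""


class XylograftError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(XylograftError, ValueError):
    """An argument violates a documented precondition (units, sign, shape)."""


class UndefinedStatisticError(XylograftError, ValueError):
    """A statistic is requested on data for which it is not defined."""


class PlacementError(XylograftError, RuntimeError):
    """Vessel placement could not satisfy the non-overlap constraint."""


class UnsupportedDesignError(XylograftError, ValueError):
    """The factorial design is unbalanced or incomplete."""


class FitFailureError(XylograftError, RuntimeError):
    """Nonlinear fit did not converge after multi-start."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateDataError(XylograftError, ValueError):
    """Data carry no information for the requested fit (constant, too short)."""


class VocabularyError(XylograftError, ValueError):
    """A graft-scoring token is outside the coding vocabulary."""


class SchemaError(XylograftError, ValueError):
    """A table is missing required columns."""


class InsufficientSampleError(XylograftError, ValueError):
    """Sample size below the validity bound of the requested test."""
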