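"""Exception hierarchy.

All package errors derive from :class:`OrdssmError` so callers can catch
broadly; the subclasses distinguish validation, numerical and Monte-Carlo
failure modes (the CLI maps them onto distinct exit codes).
"""


class OrdssmError(Exception):
    """Base class for all ordssm errors."""


class DimensionError(OrdssmError, ValueError):
    """Array arguments have incompatible or invalid shapes."""


class StationarityError(OrdssmError, ValueError):
    """A transition matrix with spectral radius >= 1 was supplied where a
    stationary process is required."""


class InfeasibleDynamicsError(OrdssmError, ValueError):
    """A stationary transition matrix is incompatible with the
    unit-marginal-variance identification constraint (the implied innovation
    covariance has a non-positive diagonal entry, or the implied marginal
    correlation matrix is not positive definite)."""


class DataError(OrdssmError, ValueError):
    """Observed data violate the declared coding (e.g. a category outside
    1..J) or table schema."""


class ParameterError(OrdssmError, ValueError):
    """An invalid model or estimator parameter value."""


class DegeneracyError(OrdssmError, RuntimeError):
    """Every particle received zero weight (impossible parameter proposal or
    catastrophic filter collapse).  Carries the timepoint, and for MIF2 the
    iteration, at which the collapse occurred."""

    def __init__(self, message, t=None, iteration=None):
        super().__init__(message)
        self.t = t
        self.iteration = iteration


class CurvatureError(OrdssmError, RuntimeError):
    """A slice-likelihood quadratic fit is convex or flat at the MLE,
    signalling (empirical) under-identification of that parameter."""


class SliceError(OrdssmError, RuntimeError):
    """Too few feasible grid points to fit a slice likelihood."""
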