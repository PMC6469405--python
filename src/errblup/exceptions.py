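"""Exception hierarchy.

All errors raised on bad user input derive from :class:`ErrblupError`
(itself a ``ValueError``) so callers can catch one base class.
"""


class ErrblupError(ValueError):
    """Base class for all package-specific errors."""


class LoadError(ErrblupError):
    """A marker/phenotype file could not be parsed into a clean matrix."""


class DimensionError(ErrblupError):
    """Shapes or label sets do not line up."""


class CodingError(ErrblupError):
    """Marker codings of two objects are incompatible (shift mismatch)."""


class CompletenessError(ErrblupError):
    """A polynomial translation generated a monomial the model cannot hold."""


class UnsupportedDegreeError(ErrblupError):
    """Monomial enumeration requested outside total degree {1, 2}."""


class SingularSystemError(ErrblupError):
    """The (penalized) normal-equations matrix is numerically singular."""


class ConvergenceError(ErrblupError):
    """An iterative solver did not converge within its iteration budget."""

    def __init__(self, message: str, iterations: int | None = None,
                 trajectory=None):
        super().__init__(message)
        self.iterations = iterations
        self.trajectory = trajectory


class DegenerateKernelError(ErrblupError):
    """A kernel is identically zero where a nonzero one is required."""


class ZeroVarianceError(ErrblupError):
    """A variance component is zero, making its penalty factor infinite."""


class InfeasibleConfigError(ErrblupError):
    """An experiment configuration cannot be run as specified."""
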