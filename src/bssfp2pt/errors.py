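"""Exception hierarchy shared across the package."""


class Bssfp2ptError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(Bssfp2ptError, ValueError):
    """A physical or geometric parameter is outside its valid domain."""


class InputError(Bssfp2ptError, ValueError):
    """Inputs are malformed or mutually inconsistent (shape mismatch, empty list)."""


class ConvergenceError(Bssfp2ptError, RuntimeError):
    """An iterative solver failed to converge within its iteration cap."""

    def __init__(self, message: str, last_residual: float | None = None):
        super().__init__(message)
        self.last_residual = last_residual


class StatisticsError(Bssfp2ptError, ValueError):
    """Too few observations (or degenerate variance) for the requested statistic."""


class EmptyMaskError(Bssfp2ptError, ValueError):
    """An operation produced or received an empty region of interest."""


class NoEnhancementError(Bssfp2ptError, ValueError):
    """Quantity is undefined because no voxel is classified as enhanced.

    Raised so that an undefined transmurality is never silently conflated
    with a true value of 0 %.
    """


class FormatError(Bssfp2ptError, ValueError):
    """A file could not be read or lacks a required field."""
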