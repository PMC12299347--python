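"""Exception and warning types shared across the package."""


class ClleachError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ClleachError, ValueError):
    """An argument is outside the physically meaningful domain."""


class InsufficientDataError(ClleachError, ValueError):
    """Too few (or too degenerate) observations for the requested fit."""


class SingularDesignError(ClleachError, ValueError):
    """The regression design matrix is rank deficient.

    Carries the names of the offending columns when they can be identified.
    """

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = columns


class DegenerateModelError(ClleachError, ValueError):
    """A model coefficient needed for an inversion is zero."""


class NoLeachingTrendError(ClleachError, ValueError):
    """Efficiency does not increase with rainfall; no critical rain exists."""


class SchemeInfeasibleError(ClleachError, ValueError):
    """The KCl-derived K2O exceeds the basal K2O target."""

    def __init__(self, message: str, max_feasible_cl_rate: float):
        super().__init__(message)
        self.max_feasible_cl_rate = max_feasible_cl_rate


class OutOfRangeWarning(UserWarning):
    """A derived fraction fell outside [0, 1]; value kept, not clamped."""
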