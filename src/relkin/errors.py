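"""Exception and warning hierarchy shared across the package."""


class RelkinError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RelkinError, ValueError):
    """Evaluation outside the mathematical domain (e.g. t <= 0)."""


class NoFiniteAdvectiveTimescale(DomainError):
    """V = 0: no finite advective time scale; the short-time regime is global."""


class ValidationError(RelkinError, ValueError):
    """Input data or configuration violates a documented contract."""


class ScheduleMismatchError(ValidationError):
    """Measured sample times do not match the sampling protocol."""

    def __init__(self, message: str, offending_times=()):
        super().__init__(message)
        self.offending_times = tuple(offending_times)


class InsufficientDataError(ValidationError):
    """Too few data points for the requested operation."""


class RangeError(ValidationError):
    """Query outside the supported range (e.g. extrapolation request)."""


class StabilityError(RelkinError):
    """Finite-difference grid violates the scheme's stability bound."""


class NumericalFailure(RelkinError):
    """A numerical routine produced NaN/Inf or failed to converge."""


class DataQualityWarning(UserWarning):
    """Measured profile violates a soft invariant (bounds, monotonicity)."""


class IdentifiabilityWarning(UserWarning):
    """Fit requested on data that poorly constrains the parameters."""
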