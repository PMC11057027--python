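"""Exception hierarchy shared across the package."""


class MeltkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MeltkinError, ValueError):
    """A physical parameter violates its documented constraints."""


class CalibrationError(MeltkinError):
    """Thermal calibration could not satisfy the requested anchors."""

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class IntegrationError(MeltkinError):
    """The ODE integrator failed to converge on a pulse segment."""


class NeverMeltsError(MeltkinError):
    """The simulated trajectory never reaches (or completes) melting."""


class SearchFailureError(MeltkinError):
    """A root/bisection search could not bracket its target."""


class ConditioningError(MeltkinError):
    """A linear system is too ill-conditioned to solve reliably."""


class NotAttainableError(MeltkinError):
    """A requested threshold lies outside the range of the fitted model."""


class DatasetFormatError(MeltkinError):
    """A dataset on disk is missing files or cannot be parsed."""
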