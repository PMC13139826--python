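"""Exception types shared across the package."""


class DDTaskError(Exception):
    """Base class for all package errors."""


class InvalidTrialError(DDTaskError):
    """A trial violates basic constraints (non-positive reward or delay)."""


class CalibrationError(DDTaskError):
    """The trial generator cannot reach the requested optimality rate."""


class InsufficientDataError(DDTaskError):
    """Too few trials or indifference points to estimate a quantity."""


class SeparationError(DDTaskError):
    """Perfect separation in a logistic regression; estimates unbounded."""


class ValidationError(DDTaskError):
    """A configuration or input file failed validation."""
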