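"""Exception hierarchy shared across the package."""


class RtceaError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(RtceaError):
    """A typed input violates one of its documented invariants."""


class RangeError(ValidationError):
    """A (low, base, high) triple is not ordered low <= base <= high."""


class ConfigurationError(RtceaError):
    """Settings are internally inconsistent (e.g. non-integer cycle count)."""


class CalibrationError(RtceaError):
    """Milestone pairs cannot be solved for a valid Weibull model."""


class InsufficientDataError(RtceaError):
    """Too few usable points to fit a survival model."""


class InfeasibleMomentsError(RtceaError):
    """Mean/range pair admits no beta distribution (variance too large)."""
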