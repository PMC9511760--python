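"""Exception hierarchy shared across the package."""


class CapeceaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CapeceaError):
    """A config file or TrialConfig failed schema parsing (names the offending key)."""


class ValidationError(CapeceaError):
    """A parsed object violates a model invariant (bounds, ordering, ...)."""


class DomainError(CapeceaError):
    """An argument lies outside the mathematical domain of an operation."""


class EstimationError(CapeceaError):
    """A statistical fit failed (non-convergence, degenerate input)."""


class CalibrationError(CapeceaError):
    """Survival-curve time-scale calibration has no feasible solution."""
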