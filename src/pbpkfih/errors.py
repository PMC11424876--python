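"""Exception hierarchy shared across the package."""


class PKError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PKError):
    """Malformed input file: missing columns, unparseable rows."""


class ValidationError(PKError):
    """Data violates a structural invariant (duplicate times, flow imbalance...)."""


class NoQuantifiableData(PKError):
    """A profile contains no concentration above the limit of quantification."""


class InsufficientData(PKError):
    """Too few points for the requested computation."""


class DomainError(PKError):
    """Numeric input outside the mathematical domain of an operation."""


class CalibrationError(PKError):
    """Model calibration could not reach its targets within the bracket."""


class SolverError(PKError):
    """ODE integration failed."""
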