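"""Exception hierarchy shared across the package."""


class KPIBenchError(Exception):
    """Base class for all package-specific errors."""


class ConversionError(KPIBenchError, ValueError):
    """Raised when an orientation conversion is undefined for the input
    (non-positive values, missing nominant target, double conversion)."""


class DegenerateInputError(KPIBenchError, ValueError):
    """Raised for inputs on which a formula degenerates (all-zero impact
    matrix, zero score vector, zero benchmark component)."""


class ConvergenceError(KPIBenchError, ArithmeticError):
    """Raised when the total-influence geometric series does not converge,
    i.e. the normalized impact matrix has spectral radius >= 1."""
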