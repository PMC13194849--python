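"""Exception hierarchy shared across the package."""


class DynTacError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DynTacError, ValueError):
    """Raised when an argument violates a documented precondition."""


class OutOfRangeError(InvalidInputError):
    """Raised when a query point falls outside a curve's support."""


class DegenerateInputError(InvalidInputError):
    """Raised when data are formally valid but carry no usable signal."""


class ConvergenceError(DynTacError, RuntimeError):
    """Raised when an iterative procedure fails to converge."""


class SchemaError(InvalidInputError):
    """Raised when a file does not match the expected column schema."""
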