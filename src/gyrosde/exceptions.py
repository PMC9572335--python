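"""Exception hierarchy shared across the package."""


class GyroSDEError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(GyroSDEError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDataError(GyroSDEError, ValueError):
    """Input data is degenerate (e.g. a zero-variance channel)."""


class NotFittedError(GyroSDEError, RuntimeError):
    """A component was used before being fitted/trained."""


class OptimizationFailureError(GyroSDEError, RuntimeError):
    """An optimization diverged or produced non-finite values."""


class FormatError(GyroSDEError, ValueError):
    """A file does not conform to the expected format."""


class ParseError(FormatError):
    """A file conforms structurally but a cell failed to parse."""
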