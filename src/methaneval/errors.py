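"""Exception hierarchy.

Exit-code mapping used by the CLI: validation problems -> 1,
I/O problems -> 2, anything else -> 3.
"""


class MethanevalError(Exception):
    """Base class for all package errors."""


class ValidationError(MethanevalError):
    """Input data violates a documented invariant."""


class ConfigurationError(MethanevalError):
    """Bad configuration: missing column, unknown key, bad parameter."""


class ParseError(ValidationError):
    """A field could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DietLookupError(ValidationError):
    """A record references a diet_id absent from the diet table."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(ValidationError):
    """Zero-variance or otherwise degenerate series where a ratio/regression is undefined."""
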