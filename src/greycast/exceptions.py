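"""Exception hierarchy for greycast.

All library errors derive from :class:`GreycastError` so callers can catch
everything the package raises with a single except clause.  Validation
problems additionally derive from ``ValueError`` to behave well in generic
code.
"""


class GreycastError(Exception):
    """Base class for all greycast errors."""


class ValidationError(GreycastError, ValueError):
    """A domain object violates one of its invariants."""


class YearGapError(ValidationError):
    """Years are not strictly consecutive (missing or duplicated year)."""


class DomainError(ValidationError):
    """A value lies outside the mathematical domain of an operation."""


class ParseError(GreycastError, ValueError):
    """An input file row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InsufficientDataError(ValidationError):
    """Series too short for the requested model (NDGM needs n >= 4)."""


class SingularSystemError(GreycastError):
    """The least-squares design matrix is rank deficient."""


class GenerationError(GreycastError):
    """Synthetic-series generation produced a non-positive annual value."""
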