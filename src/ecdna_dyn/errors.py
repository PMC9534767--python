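"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors exit 2 (handled by click),
:class:`ValidationError` exits 3, :class:`NumericalError` exits 4.
"""


class EcdnaDynError(Exception):
    """Base class for all package errors."""


class ParameterError(EcdnaDynError, ValueError):
    """A model or configuration parameter is outside its admissible range."""


class ValidationError(EcdnaDynError, ValueError):
    """An input table or config file failed schema/content validation."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input table."""


class BadValueError(ValidationError):
    """A cell of an input table has an out-of-domain value (names the row)."""


class DuplicateIdError(ValidationError):
    """An id column contains repeated identifiers."""


class EmptyTableError(ValidationError):
    """An input table has a header but no data rows."""


class NumericalError(EcdnaDynError, RuntimeError):
    """A numerical procedure failed (truncation leak, step control, ...)."""


class TruncationError(NumericalError):
    """Probability mass leaked past the copy-number truncation bound."""


class NotEstimableError(EcdnaDynError, ValueError):
    """A summary statistic is not estimable from the given data."""
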