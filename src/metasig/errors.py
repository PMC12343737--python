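"""Exception hierarchy shared across the package."""


class MetasigError(Exception):
    """Base class for all package errors."""


class FormatError(MetasigError):
    """A file does not conform to the expected tabular format."""


class RowParseError(FormatError):
    """A specific data row could not be parsed.

    Carries the 1-based line number of the offending row (header = line 1).
    """

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ValidationError(MetasigError):
    """A parsed value violates a domain invariant."""


class ParameterError(MetasigError):
    """An operation was called with an out-of-range parameter."""


class DegenerateInputError(MetasigError):
    """Input is structurally valid but unusable (e.g. all-zero matrix)."""


class UnsupportedVariantError(MetasigError):
    """Operation defined only for SNVs received an indel."""


class ContextError(MetasigError):
    """Trinucleotide context missing or inconsistent with the record."""


class AlignmentError(MetasigError):
    """Two matrices do not share the required channel ordering."""


class ConvergenceError(MetasigError):
    """Iterative fit failed to converge within the iteration budget."""

    def __init__(self, message: str, last_estimate=None):
        super().__init__(message)
        self.last_estimate = last_estimate


class UndefinedTestError(MetasigError):
    """Requested statistic is undefined for the given data (e.g. no events)."""


class ConfigError(MetasigError):
    """Pipeline configuration failed schema validation."""

    def __init__(self, message: str, keys=()):
        super().__init__(message)
        self.keys = tuple(keys)
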