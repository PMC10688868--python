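"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError → 2,
InsufficientDataError → 3; everything else is a bug.
"""


class NutricohortError(Exception):
    """Base class for all package errors."""


class ValidationError(NutricohortError):
    """Malformed input: bad config field, unparsable file, invariant violation."""


class ConfigurationError(ValidationError):
    """Invalid simulation or analysis configuration value."""


class FormatError(ValidationError):
    """Unparsable record in an input file; carries the offending line if known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InsufficientDataError(NutricohortError):
    """Too few observations to define the requested statistic."""


class UndefinedResultError(InsufficientDataError):
    """The statistic is undefined on this input (e.g. empty trace)."""
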