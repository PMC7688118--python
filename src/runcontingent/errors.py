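"""Exception hierarchy for input validation and pipeline failures."""


class RunContingentError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RunContingentError):
    """A file is structurally unusable (missing columns, wrong header)."""


class RowError(RunContingentError):
    """One or more rows failed to parse; carries 1-based line numbers."""

    def __init__(self, message, lines=()):
        super().__init__(message)
        self.lines = tuple(lines)


class ValidationError(RunContingentError):
    """Parsed content violates an invariant (duplicate ids, date gaps...)."""


class EmptyCohortError(RunContingentError):
    """No fish passed the run-detection criteria for a requested analysis."""
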