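"""Exception hierarchy for mirqc.

All package-specific failures derive from :class:`MirqcError` so callers can
catch one base class at pipeline boundaries.
"""


class MirqcError(Exception):
    """Base class for all mirqc errors."""


class ParseError(MirqcError):
    """A Ct or metadata table could not be parsed; names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateEntryError(MirqcError):
    """More than one measurement for the same (assay, condition) pair."""


class CtRangeError(MirqcError):
    """A Ct value outside the instrument range (0, 40]."""


class DomainError(MirqcError):
    """An argument outside its mathematical domain (e.g. nonpositive scale)."""


class ValidationError(MirqcError):
    """A container or configuration violated one of its invariants."""


class FitError(MirqcError):
    """Too little or degenerate data for a curve fit."""


class UndefinedCorrelationError(MirqcError):
    """Pearson correlation undefined: fewer than 3 pairs or zero variance."""


class DegenerateTableError(MirqcError):
    """A contingency table with a zero row or column total."""


class EmptyGroupError(MirqcError):
    """An operation received an empty condition group."""


class PipelineError(MirqcError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
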