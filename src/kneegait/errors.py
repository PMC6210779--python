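"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`KneegaitError`, so callers can distinguish domain failures from bugs.
"""


class KneegaitError(Exception):
    """Base class for all kneegait errors."""


class FormatError(KneegaitError):
    """Input file does not have the expected columns/layout."""


class ParseError(KneegaitError):
    """A cell in an input file could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class InputError(KneegaitError):
    """Data fails a precondition (too short, non-finite, ...)."""


class ParameterError(KneegaitError):
    """A configuration or function parameter is out of its valid range."""


class OrientationError(KneegaitError):
    """The recording cannot serve as a quasi-static gravity reference."""


class DomainError(KneegaitError):
    """A value is outside the mathematical domain of an operation."""


class InsufficientDataError(KneegaitError):
    """Not enough gait events to compute a summary."""


class UndefinedCorrelationError(KneegaitError):
    """Correlation of a constant series is undefined."""


class DegenerateSignalError(KneegaitError):
    """Signal has no energy where the operation needs it (e.g. harmonics)."""


class StratificationError(KneegaitError):
    """Class composition does not permit a stratified split."""


class DivisionError(KneegaitError):
    """A reference value of zero makes a relative error undefined."""


class JoinError(KneegaitError):
    """Two tables do not cover the same subjects; carries the odd ids."""

    def __init__(self, message: str, subject_ids=()):
        super().__init__(message)
        self.subject_ids = list(subject_ids)


class ConfigError(KneegaitError):
    """Unknown or invalid configuration key."""
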