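"""Exception types shared across the pipeline stages."""


class InfodemicError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(InfodemicError, ValueError):
    """A synthetic-data configuration violates its invariants."""


class AlignmentError(InfodemicError, ValueError):
    """Two daily series (or a series and a date window) cannot be aligned."""


class ProtocolViolationError(InfodemicError, ValueError):
    """The coding protocol was violated (e.g. fewer than three coders)."""


class DegenerateAgreementError(InfodemicError, ValueError):
    """Chance agreement is 1 (all ratings in one category); kappa undefined."""


class UndefinedCorrelationError(InfodemicError, ValueError):
    """A correlation is undefined because a windowed segment has zero variance."""


class UndefinedRatioError(InfodemicError, ZeroDivisionError):
    """A clinical/nucleic ratio is requested with zero nucleic-acid cases."""
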