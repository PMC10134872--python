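"""Exception hierarchy shared across the package.

All user-facing validation failures derive from :class:`InvalidInputError`
(a ``ValueError``) so callers can catch one type at pipeline boundaries.
"""


class ViametError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ViametError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(ViametError):
    """A qPCR standard curve could not be fit (e.g. non-negative slope)."""


class UnitMismatchError(InvalidInputError):
    """Two quantities with incompatible units were combined."""


class UndefinedRatioError(ViametError, ZeroDivisionError):
    """A ratio with a zero denominator was requested."""


class InvalidConfigError(InvalidInputError):
    """A run/simulation configuration failed schema validation."""

    def __init__(self, message: str, path: str = ""):
        self.path = path
        super().__init__(f"{path}: {message}" if path else message)
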