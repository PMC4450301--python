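"""Exception hierarchy.

All numeric-domain violations raise :class:`DomainError` (a ``ValueError``)
so callers can catch one type for bad parameters; structural problems with
signals raise the more specific subclasses.
"""


class FdeegError(Exception):
    """Base class for all package errors."""


class DomainError(FdeegError, ValueError):
    """A parameter is outside its mathematical domain."""


class SeriesLengthError(FdeegError, ValueError):
    """A signal is too short for the requested operation."""


class DegenerateSeriesError(FdeegError, ValueError):
    """A signal is constant (zero variance) where variability is required."""


class ExtrapolationError(FdeegError, ValueError):
    """An evaluation time lies outside the support of the supplied data."""


class ShapeError(FdeegError, ValueError):
    """Signals that must be commensurate (length / rate) are not."""


class PairingError(FdeegError, ValueError):
    """Real and predicted inputs cannot be paired one-to-one."""


class ParseError(FdeegError, ValueError):
    """A signal file could not be parsed."""


class FormatError(FdeegError, ValueError):
    """A signal file violates a format contract (e.g. non-uniform timebase)."""
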