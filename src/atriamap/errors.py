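"""Exception hierarchy shared across the package."""


class AtriamapError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AtriamapError, ValueError):
    """A parameter violates its documented precondition."""


class OutOfDomainError(AtriamapError, ValueError):
    """A spatial coordinate falls outside the simulated tissue domain."""


class FormatError(AtriamapError, ValueError):
    """An on-disk file does not conform to the documented format."""


class ResolutionError(AtriamapError, ValueError):
    """The sampling rate is too coarse for the requested waveform placement."""


class InsufficientDataError(AtriamapError, ValueError):
    """Too few annotated channels / values to compute the requested statistic."""


class UndefinedStatisticError(AtriamapError, ZeroDivisionError):
    """A ratio statistic is undefined (e.g. CHI on a perfectly uniform map)."""


class NoActionPotentialError(AtriamapError, ValueError):
    """The voltage trace contains no identifiable action potential."""


class IncompleteRepolarizationError(AtriamapError, ValueError):
    """The trace never repolarizes to the requested level."""


class InvalidProtocolError(AtriamapError, ValueError):
    """A pacing-protocol event sequence violates the protocol contract."""
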