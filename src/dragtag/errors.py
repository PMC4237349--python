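"""Exception and warning hierarchy for dragtag.

Exit-code mapping used by the CLI: schema errors -> 2, insufficient
data -> 3, configuration errors -> 4.
"""


class DragtagError(Exception):
    """Base class for all dragtag errors."""


class DomainError(DragtagError, ValueError):
    """An argument is outside the physically meaningful domain."""


class InsufficientDataError(DragtagError, ValueError):
    """Too few observations to perform the requested fit."""


class FitError(DragtagError, RuntimeError):
    """A model fit failed to converge; carries solver diagnostics."""


class ProtocolViolationError(DragtagError, ValueError):
    """A fatigue-protocol record is inconsistent with the protocol."""


class PairingError(DragtagError, ValueError):
    """Control and treatment records cannot be matched by individual."""


class SchemaError(DragtagError, ValueError):
    """A delimited-text input does not match its declared schema."""


class ConfigError(DragtagError, ValueError):
    """A run-configuration file is invalid."""


class UndefinedFrequencyError(DragtagError, ValueError):
    """A lateral-motion signal has too few oscillation cycles."""


class UndefinedWaveError(DragtagError, ValueError):
    """No usable phase lag between two body sites (e.g. zero lag)."""


class ExtrapolationWarning(UserWarning):
    """A prediction was requested outside the calibrated/fitted range."""


class OutOfRangeWarning(UserWarning):
    """An evaluation speed lies outside the calibration speed range."""
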