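"""Exception hierarchy used across the package."""


class LigmodeError(Exception):
    """Base class for all package errors."""


class UsageError(LigmodeError):
    """Invalid arguments or parameters supplied by the caller."""


class SelectionSyntaxError(UsageError):
    """Malformed selection expression; carries the character position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ParseError(LigmodeError):
    """A structure or trajectory file could not be parsed."""


class StructureError(LigmodeError):
    """Inconsistent molecular structure (atom counts, correspondence...)."""


class TrajectoryIOError(LigmodeError):
    """Trajectory file unreadable or truncated."""


class DegenerateFitError(LigmodeError):
    """Too few atoms (< 3) for a rigid-body superposition."""


class SpecError(LigmodeError):
    """Invalid synthetic-data specification."""


class ScheduleError(SpecError):
    """Invalid synthetic water-exchange event schedule."""


class ConfigError(LigmodeError):
    """Invalid pipeline or cavity configuration."""
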