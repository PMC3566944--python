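"""Exception hierarchy.

Every stage raises a subclass of :class:`StimmodError`, so pipeline callers
can catch one type and report the failing stage.
"""


class StimmodError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StimmodError, ValueError):
    """An invalid simulation or pipeline configuration field."""


class ParseError(StimmodError, ValueError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DesignError(StimmodError, ValueError):
    """A sample design problem (unpaired columns, missing conditions)."""


class CalibrationError(StimmodError, ValueError):
    """Array calibration cannot proceed (e.g. a constant array)."""


class ModerationError(StimmodError, ValueError):
    """Empirical-Bayes variance moderation cannot proceed."""


class ProjectionError(StimmodError, ValueError):
    """Module projection cannot proceed (e.g. insufficient gene overlap)."""
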