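"""Exception hierarchy for firegrade.

Every error the library raises deliberately derives from
:class:`FireGradeError`, so callers (and the CLI) can distinguish
domain failures from programming errors.
"""


class FireGradeError(Exception):
    """Base class for all firegrade errors."""


class ValidationError(FireGradeError, ValueError):
    """An input value is outside its documented domain."""


class DegenerateDataError(FireGradeError, ValueError):
    """The data admit no meaningful fit (e.g. all scores identical)."""


class FittingError(FireGradeError, RuntimeError):
    """The optimiser failed to converge."""


class EmptyDayError(FireGradeError, ValueError):
    """A daily aggregation was requested on an empty record set."""


class LowCoverageError(FireGradeError, ValueError):
    """A day has fewer records than the configured minimum coverage.

    The partial summary is attached so callers can decide to keep it.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class SequenceError(FireGradeError, ValueError):
    """Daily summaries are not consecutive where consecutiveness is required."""


class StateError(FireGradeError, RuntimeError):
    """An operation was invoked before required state was computed."""


class EncodingError(FireGradeError, ValueError):
    """A record cannot be packed into a telemetry frame."""


class DecodingError(FireGradeError, ValueError):
    """A telemetry frame payload is malformed, truncated or corrupt."""


class EmptyReportError(FireGradeError, ValueError):
    """A statement was requested on empty input."""
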