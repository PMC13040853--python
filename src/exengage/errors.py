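"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`ExengageError` so callers can catch
pipeline failures without masking programming errors.
"""


class ExengageError(Exception):
    """Base class for all package errors."""


class UnsupportedExerciseError(ExengageError):
    """The exercise name is not in the supported rule set."""


class MissingDataError(ExengageError):
    """Required joint markers are missing and cannot be interpolated."""


class ModeError(ExengageError):
    """Operation applied to an exercise of the wrong mode (timed vs reps)."""


class ConfigurationError(ExengageError):
    """Invalid or incomplete configuration (missing rules, definitions...)."""


class SchemaError(ExengageError):
    """An input file does not conform to the expected schema."""


class OrderingError(SchemaError):
    """Timestamps are not strictly increasing."""


class ScheduleError(ExengageError):
    """A condition schedule contains unknown labels or is inadmissible."""


class DesignViolationError(ExengageError):
    """Observed schedule is not a member of the declared randomization space."""


class InsufficientDataError(ExengageError):
    """Too few observations for the requested statistic."""


class PairingError(InsufficientDataError):
    """Paired samples have mismatched lengths."""


class DegenerateDataError(ExengageError):
    """Data carry no variance where variance is required."""
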