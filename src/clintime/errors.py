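"""Exception hierarchy shared across the package."""


class ClintimeError(Exception):
    """Base class for all errors raised by this package."""


class CannotRefineError(ClintimeError):
    """A timestamp was asked for at a finer granularity than it carries."""


class RangeDurationError(ClintimeError):
    """A range duration ("2-3 months") was used where exact arithmetic is required."""


class SchemaError(ClintimeError):
    """An annotation document or gold standard violates the published schema."""


class InconsistencyError(ClintimeError):
    """The temporal constraint network admits a strict cycle.

    ``cycle`` holds one minimal offending cycle as a list of points.
    """

    def __init__(self, message, cycle=None):
        super().__init__(message)
        self.cycle = list(cycle) if cycle is not None else []


class TimestampConflictError(ClintimeError):
    """Two derivations of the same point's timestamp disagree at their common granularity."""


class InsufficientInformationError(ClintimeError):
    """A requested duration cannot be resolved from the annotated evidence."""


class InsufficientPrecisionError(ClintimeError):
    """Only range-valued evidence exists for a requested duration."""


class InconsistentOffsetsError(ClintimeError):
    """Two derivation paths for the same duration disagree at the output unit."""
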