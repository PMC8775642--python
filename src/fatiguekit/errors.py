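"""Exception hierarchy for fatiguekit.

Every error raised by the library derives from :class:`FatigueKitError`
so callers can catch the whole family at a pipeline boundary.
"""


class FatigueKitError(Exception):
    """Base class for all fatiguekit errors."""


class SchemaError(FatigueKitError):
    """A CSV or config file does not match the expected schema."""


class RecordError(FatigueKitError):
    """A data record violates a domain invariant (carries row context)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class PartitionError(FatigueKitError):
    """A trial's condition does not belong to any configured partition."""


class SingularFitError(FatigueKitError):
    """The design matrix of a regression is singular (e.g. constant x)."""


class SampleSizeError(FatigueKitError):
    """Fewer observations than parameters to estimate."""


class FitError(FatigueKitError):
    """A model fit could not be performed on the given data."""


class DomainError(FatigueKitError):
    """An argument is outside the mathematical domain of an operation."""
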