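"""Exception hierarchy shared across the pipeline.

``ConfigError`` and ``ValidationError`` map to CLI exit code 2, I/O failures
to exit code 3; everything else is a programming error and propagates.
"""


class EthopharmError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EthopharmError):
    """A configuration object violates its invariants."""


class ValidationError(EthopharmError):
    """Input data violate a schema or range invariant."""


class InsufficientDataError(ValidationError):
    """Too few records to compute a measure (e.g. < 2 trials per paw)."""


class DegenerateSampleError(EthopharmError):
    """A statistic is undefined on this sample (e.g. zero variance)."""


class DegenerateColumnError(DegenerateSampleError):
    """A measure column is constant; carries the offending column name."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"column {column!r} is constant; correlation undefined")
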