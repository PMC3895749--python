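"""Exception hierarchy shared across the package."""


class RiverbioError(Exception):
    """Base class for all package-specific errors."""


class InvalidSampleError(RiverbioError, ValueError):
    """An abundance vector is empty, all-zero, or otherwise malformed."""


class DegenerateSampleError(RiverbioError, ValueError):
    """A sample is too small for the requested index (e.g. N <= 1 for Margalef)."""


class DuplicateSampleError(RiverbioError, ValueError):
    """Two rows share the same (station, month) key."""


class UndefinedCorrelationError(RiverbioError, ValueError):
    """Pearson correlation requested for a constant column."""


class InvalidKError(RiverbioError, ValueError):
    """K-means called with more clusters than samples (or k < 1)."""


class AmbiguousSeasonError(RiverbioError, ValueError):
    """Winter samples split evenly between clusters; exclusion is ambiguous."""


class InsufficientDataError(RiverbioError, ValueError):
    """Too few rows for the requested decomposition or summary."""


class InvalidSplitError(RiverbioError, ValueError):
    """A train/validation split would leave one part empty."""


class MalformedTreeError(RiverbioError, ValueError):
    """An expression tree references an unbound variable or is structurally broken."""


class TreeParseError(RiverbioError, ValueError):
    """A prefix expression string could not be parsed."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UndefinedEquationError(RiverbioError, ValueError):
    """The closed-form diversity equation was evaluated at a zero denominator."""


class ConfigError(RiverbioError, ValueError):
    """An analysis configuration file contains unknown or invalid keys."""


class ParseError(RiverbioError, ValueError):
    """A CSV cell or header failed validation; carries row/column coordinates."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))
        self.row = row
        self.column = column


class PipelineStageError(RiverbioError, RuntimeError):
    """Wraps a failure inside full_pipeline with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
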