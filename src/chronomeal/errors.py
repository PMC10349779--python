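"""Exception hierarchy for the chronomeal pipeline.

Every stage raises a subclass of :class:`ChronomealError` so that the
pipeline driver can attach stage and participant context before
propagating.
"""


class ChronomealError(Exception):
    """Base class for all package errors."""


class SchemaError(ChronomealError):
    """An input table is missing a required column or has an invalid header."""


class RowParseError(ChronomealError):
    """A single row of an input table could not be parsed.

    Carries the 1-based line number (header = line 1) in ``line``.
    """

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class UndefinedCVError(ChronomealError):
    """Coefficient of variation requested for a pair of zero totals."""


class ReconciliationError(ChronomealError):
    """Dual-entry reconciliation could not be completed for a recall day."""


class InputError(ChronomealError):
    """A scalar computation received physiologically impossible input."""


class DegenerateInputError(ChronomealError):
    """A regression input has zero variance or too few complete pairs."""


class CollinearityError(ChronomealError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class StratumError(ChronomealError):
    """A sex stratum is too small or missing for a stratified computation."""


class ClassificationError(ChronomealError):
    """Breakfast classification requires exactly three recall days."""


class PipelineError(ChronomealError):
    """A stage failed inside the orchestrated pipeline; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
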