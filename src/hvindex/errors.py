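"""Exception hierarchy for the HVI assessment pipeline."""


class HVIError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HVIError):
    """Invalid indicator schema (duplicate ids, unknown component, ...)."""


class RosterError(HVIError):
    """District/province roster inconsistency."""


class TableParseError(HVIError):
    """A delimited indicator table could not be parsed.

    Carries the offending row/column coordinates when known.
    """

    def __init__(self, message: str, *, row: str | None = None,
                 column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class ConfigError(HVIError):
    """Invalid assessment configuration."""


class PipelineError(HVIError):
    """Failure inside a pipeline stage; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
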