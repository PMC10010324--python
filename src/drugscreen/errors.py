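"""Exception types shared across the package."""


class DrugscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DrugscreenError):
    """Invalid configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class SchemaError(DrugscreenError):
    """Registry file violates the expected schema.

    Carries the file, the 1-based data line (header excluded) and, where
    known, the offending column.
    """

    def __init__(self, file: str, message: str, line: int | None = None,
                 column: str | None = None):
        self.file = file
        self.line = line
        self.column = column
        loc = file
        if line is not None:
            loc += f", row {line}"
        if column is not None:
            loc += f", column '{column}'"
        super().__init__(f"{loc}: {message}")


class FitError(DrugscreenError):
    """Model cannot be fitted on the given design."""


class NoExposedSubjectsError(FitError):
    """Every subject in the design is a never-user of the target drug."""
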