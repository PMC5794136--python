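"""Exception types shared across the package."""


class PregepiError(Exception):
    """Base class for all package errors."""


class SchemaError(PregepiError):
    """A table is missing a required column or has an unusable layout."""

    def __init__(self, table: str, message: str):
        self.table = table
        super().__init__(f"{table}: {message}")


class RowError(PregepiError):
    """A single row could not be parsed; carries table name and line number."""

    def __init__(self, table: str, line: int, message: str):
        self.table = table
        self.line = line
        super().__init__(f"{table}, line {line}: {message}")


class ConfigurationError(PregepiError):
    """An algorithm configuration table is incomplete or inconsistent."""


class ValidationError(PregepiError):
    """Domain-level invariant violated (bad episode, bad simulation config...)."""
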