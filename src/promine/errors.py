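"""Exception hierarchy shared by all pipeline stages."""


class PromineError(Exception):
    """Base class for all package errors."""


class SchemaError(PromineError):
    """A file header does not match the declared dialect."""


class RowParseError(PromineError):
    """A row contains an unparsable date or number (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class IntegrityError(PromineError):
    """Data violates a structural invariant (duplicate keys, bad ordering)."""


class ConfigError(PromineError):
    """An invalid configuration value or unknown catalog name."""
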