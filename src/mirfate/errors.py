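"""Exception hierarchy.

``MirfateError`` is the root; the CLI maps ``ValidationError`` (and its
subclasses) to exit code 2 and everything else to exit code 1.
"""


class MirfateError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MirfateError):
    """Invalid input values: bad alphabets, malformed tables, bad arguments."""


class ConfigError(ValidationError):
    """A simulation or run configuration field is out of its domain."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class SchemaError(ValidationError):
    """A file does not conform to its expected schema (missing columns etc.)."""
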