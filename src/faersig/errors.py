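"""Exception hierarchy.

CLI exit-code convention: :class:`ConfigError` is a user error (exit 1);
ingest/estimate failures are data errors (exit 2).
"""


class FaersigError(Exception):
    """Base class for all package errors."""


class ConfigError(FaersigError):
    """Invalid configuration or rejected input value (user error)."""


class IngestError(FaersigError):
    """Fatal ingest failure: missing file, unreadable input."""


class SchemaError(IngestError):
    """A required column is absent from a file header."""


class EstimateError(FaersigError):
    """A disproportionality estimate is undefined for the given table."""
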