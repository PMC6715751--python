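"""Exception hierarchy shared across the pipeline stages."""


class ScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(ScreenError):
    """Invalid configuration (bad proportions, missing thresholds, ...)."""


class SchemaError(ScreenError):
    """A table violates its schema (missing column, bad value, bad label)."""


class ParseError(ScreenError):
    """A file could not be parsed (malformed GMT line, bad header, ...)."""


class QCError(ScreenError):
    """A plate fails a structural QC precondition (e.g. no usable siNC wells)."""
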