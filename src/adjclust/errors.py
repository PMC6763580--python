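"""Exception types shared across the pipeline."""


class AdjClustError(Exception):
    """Base class for package errors."""


class SchemaError(AdjClustError):
    """Input data does not match the expected schema (missing markers, etc.)."""


class StateError(AdjClustError):
    """Operation applied to data in the wrong state (e.g. double transform)."""


class ArgumentError(AdjClustError, ValueError):
    """Invalid argument value."""
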