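"""Exception hierarchy shared across the toolkit."""


class StriakitError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(StriakitError, ValueError):
    """A simulation or pipeline configuration violates its preconditions."""


class DataError(StriakitError, ValueError):
    """An input table or trace is malformed or degenerate."""


class DetectionError(StriakitError, RuntimeError):
    """Event detection cannot proceed (e.g. empty filtered trace)."""
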