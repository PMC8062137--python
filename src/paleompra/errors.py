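"""Exception hierarchy shared across the pipeline stages."""


class PaleompraError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PaleompraError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(PaleompraError):
    """A required column is missing from an input table."""


class InputError(PaleompraError):
    """An input violates a precondition (wrong length, empty, out of range)."""


class DataIntegrityError(PaleompraError):
    """Input data contradicts itself (e.g. reference base matches neither allele)."""


class DegenerateNullError(PaleompraError):
    """The empirical null distribution is degenerate (zero spread)."""
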