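"""Exception types shared across the package."""


class MbomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MbomicsError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(MbomicsError, ValueError):
    """Malformed or degenerate input data (duplicates, negatives, all-missing rows...)."""


class PipelineOrderError(MbomicsError, RuntimeError):
    """A preprocessing operation was applied out of order (normalize -> impute -> log -> autoscale)."""


class LeakageError(MbomicsError, RuntimeError):
    """A held-out evaluation would reuse training subjects."""
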