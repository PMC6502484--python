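"""Exception hierarchy shared across the pipeline stages."""


class RicegsError(Exception):
    """Base class for all package errors."""


class ConfigError(RicegsError):
    """An invalid configuration value; the message names the offending field."""


class DataError(RicegsError):
    """Input data violates a precondition (empty result, misaligned ids...)."""


class FormatError(DataError):
    """A file could not be parsed in the declared dialect."""


class ConvergenceError(RicegsError):
    """An iterative solver failed to converge."""
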