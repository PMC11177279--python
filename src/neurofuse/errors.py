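"""Package-wide exception types."""


class NeurofuseError(Exception):
    """Base class for all package errors."""


class ConfigError(NeurofuseError, ValueError):
    """Invalid configuration (counts, fractions, bounds)."""


class LeakageError(NeurofuseError):
    """A fitting operation was offered rows reserved for the held-out test set."""


class StatsParseError(NeurofuseError, ValueError):
    """Malformed morphometry stats table."""


class ChannelError(NeurofuseError, ValueError):
    """A signal channel is unusable (constant / zero variance)."""
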