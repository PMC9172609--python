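"""Exception hierarchy shared across the package."""


class SurgecastError(Exception):
    """Base class for all surgecast errors."""


class ValidationError(SurgecastError, ValueError):
    """Invalid input data (malformed CSV rows, negative counts, bad ranges)."""


class ConfigurationError(SurgecastError, ValueError):
    """Invalid configuration value, key or mode."""


class InsufficientHistoryError(SurgecastError, ValueError):
    """Not enough historic observations to produce a forecast."""
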