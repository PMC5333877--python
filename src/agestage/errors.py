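"""Exception types shared across the package."""


class AgestageError(Exception):
    """Base class for all package errors."""


class DataError(AgestageError):
    """Malformed or inconsistent input data (bad CSV row, invalid record)."""


class ConfigError(AgestageError):
    """Invalid configuration (missing seed, bad scheme, bad spec)."""


class EstimationError(AgestageError):
    """A parameter is undefined for the given schedules (e.g. r when R0 = 0)."""
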