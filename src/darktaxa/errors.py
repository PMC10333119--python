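"""Exception hierarchy shared across the pipeline stages."""


class DarkTaxaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DarkTaxaError):
    """Invalid configuration or scenario parameters."""


class DataError(DarkTaxaError):
    """Malformed or inconsistent input data."""


class InsufficientOverlapError(DataError):
    """Two aligned sequences share fewer comparable positions than required."""
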