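"""Exception types shared across the package."""


class OrthobinError(Exception):
    """Base class for all package errors."""


class FormatError(OrthobinError):
    """Malformed or invariant-violating input data."""


class ConfigError(OrthobinError):
    """Invalid pipeline or simulation configuration."""
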