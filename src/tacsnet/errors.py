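"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a configuration value or combination is invalid."""


class NumericError(RuntimeError):
    """Raised when a simulation state becomes non-finite."""
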