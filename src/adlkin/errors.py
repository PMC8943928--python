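"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent or out of range."""


class ValidationError(ValueError):
    """Input data violates a structural invariant (shape, finiteness, order)."""
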