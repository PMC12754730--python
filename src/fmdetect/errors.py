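"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object violates one of its invariants."""


class ValidationError(ValueError):
    """Input data violate a documented schema invariant."""
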