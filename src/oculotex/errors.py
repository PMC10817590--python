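"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object violates one of its invariants."""


class DataError(ValueError):
    """Input data are inconsistent with what an operation requires."""
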