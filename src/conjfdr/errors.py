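"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A required column, parameter, or config entry is missing or invalid."""


class InputError(ValueError):
    """The input data cannot support the requested computation."""
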