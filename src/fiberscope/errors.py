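"""Exception types shared across the package."""


class InvalidConfigurationError(ValueError):
    """An endoscope, laser, or simulation configuration is physically invalid."""


class DegenerateFitError(RuntimeError):
    """A fit cannot be performed because the data carry no usable signal."""
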