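"""Package exception types."""


class InvalidSpecError(ValueError):
    """A phantom or run specification violates its invariants."""


class ConfigurationError(ValueError):
    """A model/transform configuration is inconsistent (unknown wavelet, bad ratio...)."""


class DegenerateInputError(ValueError):
    """An input is degenerate for the requested operation (e.g. constant foreground)."""


class InvalidLabelError(ValueError):
    """A label volume contains values outside the BraTS set {0, 1, 2, 4}."""
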