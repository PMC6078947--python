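"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration."""


class DataFormatError(ValueError):
    """On-disk dataset is malformed or inconsistent with its metadata."""
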