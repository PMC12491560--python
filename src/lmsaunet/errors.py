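"""Shared exception types."""


class ConfigurationError(ValueError):
    """A layer or block was configured inconsistently (channel/kernel mismatch)."""


class DimensionError(ValueError):
    """An input's spatial or channel dimensions violate an operation's contract."""


class DataError(ValueError):
    """A dataset file or array has invalid content (non-binary mask, missing pair)."""
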