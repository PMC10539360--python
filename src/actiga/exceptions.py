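class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined for this input (e.g. zero variance)."""


class ConfigError(ValueError):
    """A configuration violates one of its declared invariants."""
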