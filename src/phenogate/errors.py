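"""Shared exception types."""


class ConfigurationError(ValueError):
    """Invalid or incomplete configuration (thresholds, rules, resolutions...)."""


class PackingError(RuntimeError):
    """Cell placement failed: requested count does not fit in the image."""


class SamplingError(ValueError):
    """Balanced sampling impossible (e.g. a class has no examples)."""


class MappingError(KeyError):
    """A fine class is neither mapped to a parent nor flagged droppable."""
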