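"""Exception hierarchy shared across the pipeline."""


class EpiarrayError(Exception):
    """Base class for all epiarray errors."""


class FormatError(EpiarrayError):
    """A file does not match the expected column/record contract."""


class ConsistencyError(EpiarrayError):
    """Inputs that must agree (table vs sample sheet, joined results) do not."""


class ValidationError(EpiarrayError):
    """A parameter or value is outside its documented domain."""


class NormalizationError(EpiarrayError):
    """Spike-in normalization cannot be computed for a sample/channel."""
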