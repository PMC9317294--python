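"""Exception hierarchy shared across the pipeline stages."""


class LungScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(LungScreenError, ValueError):
    """Invalid user input: bad shapes, sizes, ratios, or class counts."""


class DegenerateImageError(ValidationError):
    """An image is spatially constant and cannot be min-max rescaled."""


class ConfigurationError(LungScreenError, ValueError):
    """Unsupported configuration value (e.g. unknown wavelet or method name)."""


class ContractViolationError(LungScreenError, RuntimeError):
    """A pluggable component broke its declared contract."""


class AlignmentError(ValidationError):
    """Feature blocks disagree on sample count, order, or labels."""
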