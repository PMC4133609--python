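"""Exception hierarchy shared across the package."""


class ProfalnError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ProfalnError):
    """A file could not be parsed in the named dialect."""


class ValidationError(ProfalnError):
    """A value or data structure violates a documented invariant."""


class DimensionError(ValidationError):
    """Shapes/lengths of related objects disagree."""


class NumericError(ProfalnError):
    """Numerical overflow/underflow that rescaling could not prevent."""


class GenerationError(ProfalnError):
    """Synthetic-data generation was asked for a degenerate configuration."""


class MetricError(ProfalnError):
    """An evaluation metric is undefined for the given inputs."""
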