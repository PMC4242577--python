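"""Exception hierarchy shared across the pipeline."""


class CphyloError(Exception):
    """Base class for all package errors."""


class FormatError(CphyloError):
    """A file does not conform to its declared format."""


class ArgumentError(CphyloError, ValueError):
    """An argument violates a documented precondition."""


class OutOfBoundsError(CphyloError):
    """A coordinate falls outside a grid extent."""


class ConfigurationError(CphyloError):
    """Run configuration is inconsistent (e.g. epoch table gaps)."""


class DegenerateDataError(CphyloError):
    """Input is formally valid but carries no usable signal."""
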