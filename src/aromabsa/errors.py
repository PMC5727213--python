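"""Exception hierarchy shared across the pipeline."""


class AromaBsaError(Exception):
    """Base class for all package errors."""


class DegenerateInputError(AromaBsaError):
    """Input is structurally valid but carries no usable information."""


class ConfigurationError(AromaBsaError):
    """A parameter combination that can never be satisfied."""


class DataFormatError(AromaBsaError):
    """Malformed or inconsistent tabular input."""


class BulkSizeError(AromaBsaError):
    """An extreme bulk came out smaller than the minimum size."""


class CollinearityError(AromaBsaError):
    """Scatter matrices are singular for the requested feature set."""


class UndefinedStatisticError(AromaBsaError):
    """A statistic (t, SD ratio, ...) is undefined for the given input."""
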