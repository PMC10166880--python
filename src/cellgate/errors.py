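"""Exception hierarchy shared across the package."""


class CellgateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CellgateError):
    """A file does not conform to its declared format (names the offending file)."""


class ValidationError(CellgateError, ValueError):
    """A container invariant is violated (dimensions, finiteness, duplicates...)."""


class DimensionalityError(ValidationError):
    """An embedding or coordinate array is not two-dimensional."""


class AxesContextError(CellgateError):
    """A polygon session's axes context does not match the dataset it is applied to."""


class FeatureLookupError(CellgateError, KeyError):
    """A requested gene/feature, embedding or annotation key does not exist."""


class DomainError(CellgateError, ValueError):
    """Values outside the mathematical domain of a transform (e.g. log10 of negatives)."""


class ConfigError(CellgateError):
    """A workflow configuration references undefined keys or paths."""
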