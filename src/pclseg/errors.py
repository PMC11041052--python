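"""Exception hierarchy shared across the pipeline stages."""


class PclsegError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(PclsegError, ValueError):
    """Arrays have incompatible or invalid shapes."""


class SizeError(PclsegError, ValueError):
    """An input is too small for the requested operation (no silent padding)."""


class DimensionalityError(PclsegError, ValueError):
    """A volume does not have exactly three spatial axes."""


class FormatError(PclsegError, ValueError):
    """A file could not be parsed in the expected format."""


class ValidationError(PclsegError, ValueError):
    """Input data violates a documented invariant (e.g. non-finite HU)."""


class ConfigurationError(PclsegError, ValueError):
    """An operation was configured inconsistently."""


class PlacementError(PclsegError, RuntimeError):
    """Phantom lesion placement failed after bounded retries."""


class DegenerateInputError(PclsegError, ValueError):
    """An input is degenerate for the operation (e.g. empty abdomen mask)."""
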