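"""Exception types shared across the package."""


class MeatspecError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MeatspecError, ValueError):
    """A file or table does not have the expected layout."""


class ValidationError(MeatspecError, ValueError):
    """Data violates a declared invariant (unknown species, inconsistent metadata, ...)."""


class DimensionError(MeatspecError, ValueError):
    """Array shapes are incompatible with the requested operation."""


class ConfigError(MeatspecError, ValueError):
    """An invalid configuration value."""


class FitError(MeatspecError, ValueError):
    """A model or transform cannot be fitted on the given data."""
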