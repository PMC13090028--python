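"""Exception hierarchy shared across the package."""


class SemdecodeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SemdecodeError, ValueError):
    """Invalid user-supplied configuration (sizes, grids, unknown keys)."""


class DataIntegrityError(SemdecodeError, ValueError):
    """Inputs that violate a dataset contract (missing features, NaNs, shapes)."""


class FormatError(SemdecodeError, ValueError):
    """A file on disk does not match the expected on-disk schema."""


class StageError(SemdecodeError, RuntimeError):
    """A pipeline stage was invoked before its upstream artifacts exist."""
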