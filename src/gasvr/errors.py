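"""Exception hierarchy shared across the package."""


class GasvrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GasvrError, ValueError):
    """A user-supplied option or precondition on configuration is invalid."""


class ValidationError(GasvrError, ValueError):
    """Input data violates a documented contract."""


class EmptyTableError(GasvrError, ValueError):
    """A cleaning step removed every feature column."""
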