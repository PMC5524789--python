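"""Exception hierarchy shared across the package."""


class MultistressError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MultistressError):
    """An invalid design, parameter set, or run configuration."""


class DataError(MultistressError):
    """Malformed or inconsistent input records."""


class ModelError(MultistressError):
    """A model could not be fitted or interrogated as requested."""
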