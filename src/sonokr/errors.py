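"""Exception hierarchy shared across the package."""


class SonokrError(ValueError):
    """Base class for all package-specific errors."""


class DomainError(SonokrError):
    """An argument is outside its mathematical domain (e.g. h <= 0, NaN input)."""


class EmptyNeighborhoodError(SonokrError):
    """A local fit was requested with no usable (positively weighted) neighbor."""


class ConfigurationError(SonokrError):
    """A configuration is self-consistent but unusable (e.g. vanishing bandwidth)."""


class FormatError(SonokrError):
    """A file could not be parsed as the expected format."""
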