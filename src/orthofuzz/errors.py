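"""Exception hierarchy shared across the package."""


class OrthofuzzError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OrthofuzzError):
    """A file does not conform to the expected dialect (syntax level)."""


class ValidationError(OrthofuzzError):
    """Well-formed input violates a domain invariant (semantic level)."""


class ConfigurationError(OrthofuzzError):
    """A run was configured in a way that cannot be executed."""
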