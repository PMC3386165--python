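"""Exception hierarchy shared across the package."""


class PerturbnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PerturbnetError):
    """A file does not have the expected overall layout."""


class ParseError(PerturbnetError):
    """A cell or line could not be interpreted; message names the location."""


class ValidationError(PerturbnetError):
    """Input values violate a documented invariant."""


class ConfigurationError(PerturbnetError):
    """Configuration values are inconsistent or out of range."""


class UsageError(PerturbnetError):
    """The caller asked for an unsupported option (e.g. unknown format)."""
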