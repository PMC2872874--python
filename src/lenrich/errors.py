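"""Exception hierarchy shared across the package."""


class LenrichError(Exception):
    """Base class for all package errors."""


class FormatError(LenrichError):
    """An input file does not conform to the expected layout."""


class ValidationError(LenrichError):
    """Input values violate a documented precondition or invariant."""


class ConfigurationError(LenrichError):
    """A run was configured inconsistently (e.g. weighted method without a PWF)."""


class DegenerateFitError(LenrichError):
    """The PWF cannot be estimated (e.g. all DE flags identical)."""
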