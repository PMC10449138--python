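"""Exception hierarchy used across the package."""


class SerotraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SerotraceError, ValueError):
    """A caller-supplied value violates a documented precondition."""


class ConfigurationError(SerotraceError, ValueError):
    """A run configuration is incomplete, inconsistent or refers to
    unknown models/parameters."""


class UnknownIdentifierError(SerotraceError, KeyError):
    """Lookup of an individual, exposure type or biomarker that does not
    exist in the referenced table."""
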