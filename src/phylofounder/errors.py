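"""Exception hierarchy shared across the package."""


class PhyloFounderError(Exception):
    """Base class for package errors."""


class AlignmentError(PhyloFounderError):
    """Malformed multiple-sequence alignment (e.g. unequal record lengths)."""


class MissingReferenceError(PhyloFounderError):
    """The designated reference record is absent from the input."""


class VariantParseError(PhyloFounderError):
    """A variant-string token does not match the notation grammar."""

    def __init__(self, token: str, message: str = ""):
        self.token = token
        super().__init__(message or f"malformed variant token: {token!r}")


class ConfigurationError(PhyloFounderError):
    """An invalid or incomplete configuration value."""


class StructureError(PhyloFounderError):
    """A graph/tree structural precondition is violated."""
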