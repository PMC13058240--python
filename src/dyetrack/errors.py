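"""Exception hierarchy shared across the package."""


class DyeTrackError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DyeTrackError):
    """A value or object violates a documented contract."""


class SchemaError(DyeTrackError):
    """A file or column map does not cover a required role."""


class ParseError(DyeTrackError):
    """A cell in an input file could not be interpreted."""
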