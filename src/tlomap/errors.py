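"""Typed exceptions raised across the package."""


class TlomapError(Exception):
    """Base class for all package errors."""


class FormatError(TlomapError):
    """A file could not be parsed in its declared format."""


class SchemaError(TlomapError):
    """A table is missing required columns or has wrong dtypes."""


class ValidationError(TlomapError):
    """Input values violate a contract (duplicates, NaN, negatives...)."""


class ParameterError(TlomapError):
    """A parameter is outside its valid range."""


class EmptyResultError(TlomapError):
    """An operation removed or excluded every record."""
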