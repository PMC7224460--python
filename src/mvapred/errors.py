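"""Exception hierarchy shared across the package."""


class MvapredError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MvapredError):
    """A file does not parse in the stated dialect (e.g. missing sampling rate)."""


class AnnotationError(MvapredError):
    """An annotation refers to a sample index outside the signal."""


class SchemaError(MvapredError):
    """A feature table is missing, or contains unresolvable, columns."""


class ConfigError(MvapredError):
    """A configuration value is invalid for the data it is applied to."""


class DataError(MvapredError):
    """Input data violate a precondition (e.g. non-positive RR interval)."""
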