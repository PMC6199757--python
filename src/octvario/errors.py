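"""Exception hierarchy shared across the package."""


class OctVarioError(Exception):
    """Base class for all package errors."""


class ValidationError(OctVarioError):
    """Input data violates a structural invariant (boundary order, shapes, ...)."""


class FormatError(OctVarioError):
    """A file is missing required keys/columns or cannot be parsed."""


class ConfigError(OctVarioError):
    """A configuration value is inconsistent or out of its admissible range."""


class UndefinedMetricError(OctVarioError):
    """A classification metric is undefined for the given confusion counts."""
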