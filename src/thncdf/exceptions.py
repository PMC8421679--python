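"""Exception hierarchy shared across the package."""


class ThncdfError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ThncdfError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(ThncdfError):
    """Parsed content violates a domain invariant."""


class AlignmentError(ThncdfError):
    """Two objects that must share an identifier ordering do not."""


class ConfigError(ThncdfError):
    """An invalid configuration value was supplied."""


class FeatureUnavailableError(ThncdfError):
    """An optional dependency required for this feature is not installed."""
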