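"""Exception hierarchy shared across the package."""


class AguadanetError(Exception):
    """Base class for all package errors."""


class ValidationError(AguadanetError, ValueError):
    """Input data violates a documented invariant (duplicate id, area <= 0, ...)."""


class FormatError(AguadanetError, ValueError):
    """A file does not conform to the expected layout (missing column, bad GeoJSON)."""


class ConfigurationError(AguadanetError, ValueError):
    """A required configuration element is missing or inconsistent."""
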