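"""Exception hierarchy shared across the package."""


class BrainprintError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BrainprintError):
    """A container is missing required metadata or has the wrong layout."""


class ValidationError(BrainprintError):
    """Data violate an invariant (NaN/Inf, bad shape, duplicate names...)."""


class DegenerateDataError(BrainprintError):
    """Data are numerically degenerate for the requested operation
    (zero-variance channel/time point/feature vector)."""


class ProtocolError(BrainprintError):
    """Source/target sets are inconsistent with the identification protocol."""


class ConfigError(BrainprintError):
    """An experiment configuration is invalid; the message lists violations."""
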