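"""Exception hierarchy shared across the package."""


class MatsipError(ValueError):
    """Base class for domain errors raised by matsip."""


class InvalidValueError(MatsipError):
    """An input value violates a physical or numerical precondition."""


class InsufficientDataError(MatsipError):
    """Too few observations to perform the requested estimate or test."""


class SchemaError(MatsipError):
    """A tabular input does not match the expected columns or mixes elements."""


class MissingBaselineError(MatsipError):
    """No control observations available to define natural abundance."""


class BelowDetectionError(MatsipError):
    """Signal below the detection floor; quantity reported missing, not zero."""


class DegenerateDesignError(MatsipError):
    """A regression design with no usable variation (e.g. identical standards)."""


class NonIdentifiableError(MatsipError):
    """A pattern carries no isotopic information (flat within tolerance)."""


class ConfigError(MatsipError):
    """Invalid or inconsistent configuration."""
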