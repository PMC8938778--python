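"""Exception hierarchy for coapvc."""


class CoapvcError(ValueError):
    """Base class for all coapvc errors."""


class GeometryError(CoapvcError):
    """Invalid or inconsistent region / phantom geometry (e.g. V_SO < V_A)."""


class InvalidParameterError(CoapvcError):
    """A scalar parameter is outside its physical domain."""


class ConfigurationError(CoapvcError):
    """Missing or contradictory configuration (e.g. vein correction without vein data)."""


class CoverageError(CoapvcError):
    """A fine-sampled curve does not cover the requested frame schedule."""


class ParseError(CoapvcError):
    """A file could not be parsed into the expected structure."""
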