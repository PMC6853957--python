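"""Exception hierarchy for specfx."""


class SpecfxError(Exception):
    """Base class for all specfx errors."""


class ConfigurationError(SpecfxError):
    """Invalid generator or analysis configuration."""


class ParseError(SpecfxError):
    """Malformed input table (missing column, duplicate row, negative area...)."""


class AmbiguityError(SpecfxError):
    """Peak matching is ambiguous (two peaks of one sample within the RT tolerance)."""


class DegenerateInputError(SpecfxError):
    """Input is degenerate for the requested operation (zero vector, constant sequence...)."""
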