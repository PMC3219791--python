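"""Exception types shared across pipeline stages."""


class DroughtseqError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DroughtseqError):
    """Malformed input file or table (wrong columns, bad values)."""


class DesignError(DroughtseqError):
    """Inconsistent experimental design (lane/sheet mismatch, bad contrast)."""


class ConfigError(DroughtseqError):
    """Invalid configuration value."""


class EstimationError(DroughtseqError):
    """A statistical estimate could not be computed from the given data."""
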