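"""Exception hierarchy."""


class SteromineError(Exception):
    """Base class for package errors."""


class InputError(SteromineError, ValueError):
    """Malformed sequence, annotation or parameter input."""


class CalibrationError(SteromineError):
    """A statistical score scale is missing or could not be fitted."""


class SimulationError(SteromineError):
    """A synthetic-data target (e.g. sequence identity) could not be realized."""


class ConfigurationError(SteromineError):
    """Inconsistent pipeline or panel configuration."""


class AnalysisError(SteromineError):
    """A downstream analysis stage has no usable input (e.g. zero complete taxa)."""
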