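"""Exception hierarchy shared across the package."""


class SlidegaitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SlidegaitError):
    """Invalid model, generator or pipeline configuration."""


class DataError(SlidegaitError):
    """Malformed input data (length mismatch, non-finite samples, ...)."""


class NoCycleError(DataError):
    """The pressure trace never crosses the onset threshold."""


class IncompleteCycleError(DataError):
    """Pressure onset was found but the trace never unloads again."""


class PlateauNotFoundError(DataError):
    """No sustained low-slope pressure segment inside the cycle."""


class DegeneratePressureError(DataError):
    """Pressure profile lacks the plateau/peak/trough/peak signature."""
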