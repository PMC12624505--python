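"""Exception types raised across the pipeline."""


class LifeTracerError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LifeTracerError):
    """A raw scan table does not conform to the expected column layout."""


class EmptyTableError(LifeTracerError):
    """A raw scan file contains no data rows."""


class ValidationError(LifeTracerError):
    """A manifest, matrix or parameter set failed validation."""


class ConfigurationError(LifeTracerError):
    """A required configuration value is missing or inconsistent."""


class CalibrationError(LifeTracerError):
    """Parameter calibration could not find an acceptable setting."""
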