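"""Exception hierarchy used across the package."""


class CqnormError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CqnormError):
    """A dataset or table violates its structural invariants."""


class ConfigurationError(CqnormError):
    """A configuration object names an invalid value; message names the field."""


class FitError(CqnormError):
    """A model fit failed (e.g. no amplification signal in a standard curve)."""


class CalibrationError(CqnormError):
    """Inter-plate calibration is impossible (calibrator missing on a plate)."""
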