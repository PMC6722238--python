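"""Exception types raised by the simulation pipeline."""


class RtisimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RtisimError):
    """A configuration value or structure is invalid."""


class CalibrationError(RtisimError):
    """Incidence calibration failed to reach its targets."""
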