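"""Exception hierarchy."""


class AcquaError(Exception):
    """Base class for package errors."""


class ValidationError(AcquaError, ValueError):
    """Invalid input data (non-finite pixels, wrong shapes, bad point sets)."""


class ConfigError(AcquaError, ValueError):
    """Invalid configuration (missing threshold, non-positive calibration...)."""
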