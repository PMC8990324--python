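"""Exception types raised across the pipeline."""


class ValenceLoopError(Exception):
    """Base class for all package-specific errors."""


class UnrepresentableBandError(ValenceLoopError, ValueError):
    """Sampling rate too low for the 10-250 Hz analysis band."""


class EmptyInputError(ValenceLoopError, ValueError):
    """An operation received an empty signal."""


class TooShortError(ValenceLoopError, ValueError):
    """Input shorter than the minimum the operation supports."""


class SolverError(ValenceLoopError, RuntimeError):
    """Newton iteration for the implicit filter update failed to converge.

    Carries the last iterate in ``last_iterate``.
    """

    def __init__(self, message: str, last_iterate: float | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


class InsufficientTrialsError(ValenceLoopError, ValueError):
    """Fewer than the required number of trials in a valence class."""


class CalibrationError(ValenceLoopError, ValueError):
    """Open-loop response does not support membership-function calibration."""


class ConfigError(ValenceLoopError, ValueError):
    """Malformed configuration (unknown labels, bad durations, ...)."""
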