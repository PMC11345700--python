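"""Exception hierarchy for awsom."""


class AwsomError(Exception):
    """Base class for all awsom errors."""


class GridError(AwsomError):
    """Invalid grid geometry (degenerate axes, inconsistent shapes)."""


class PlacementError(AwsomError):
    """Region-of-activation masks leave the brain, overlap, or sit too close."""


class CalibrationError(AwsomError):
    """HRF landmark calibration failed to achieve the requested ordering."""


class DesignError(AwsomError):
    """Stimulus design inconsistent with the scan (onsets beyond scan end, ...)."""


class GLMError(AwsomError):
    """General linear model cannot be fitted (rank deficiency, too few volumes)."""


class InferenceError(AwsomError):
    """Statistical inference failed (empty mask, non-finite statistic map)."""


class ConfigError(AwsomError):
    """Invalid or unknown configuration keys."""
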