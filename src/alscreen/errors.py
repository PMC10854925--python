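"""Exception types shared across the package."""


class AlscreenError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(AlscreenError):
    """Input too small or too uniform for the requested operation."""


class CalibrationError(AlscreenError):
    """Hit-fraction calibration could not reach the target.

    Carries the achieved fraction so callers can report how far off the
    bounded search ended up.
    """

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


class SplitError(AlscreenError):
    """An initial data split would leave an unusably small labeled set."""


class TrainingError(AlscreenError):
    """The labeled set is too small to train the ensemble."""


class SchemaError(AlscreenError):
    """A table or matrix does not match the expected layout."""


class NormalizationError(AlscreenError):
    """Per-drug normalization by the Random baseline is undefined."""


class ConfigError(AlscreenError):
    """Invalid strategy, ensemble, or benchmark configuration."""
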