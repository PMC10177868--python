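"""Exception hierarchy for the deepspectra pipeline.

Every stage raises a distinct subclass so the CLI can map failures to
distinct exit codes.
"""


class DeepspectraError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(DeepspectraError):
    """Invalid simulation / pipeline configuration."""

    exit_code = 2


class CalibrationError(DeepspectraError):
    """White/dark reference calibration is impossible at some wavelength."""

    exit_code = 3


class GroupingError(DeepspectraError):
    """Replicate-to-sample grouping refers to unknown columns."""

    exit_code = 4


class ParameterError(DeepspectraError):
    """Invalid filter / resampling parameters."""

    exit_code = 5


class SplitError(DeepspectraError):
    """Dataset division is impossible (too few samples, bad pattern)."""

    exit_code = 6


class StatsError(DeepspectraError):
    """Summary statistics undefined (empty set, singleton SD)."""

    exit_code = 7


class ArchitectureError(DeepspectraError):
    """Network shape arithmetic produced a non-positive feature-map length."""

    exit_code = 8


class DataError(DeepspectraError):
    """Spectra / target alignment or length mismatch."""

    exit_code = 9


class DivergenceError(DeepspectraError):
    """Training produced a non-finite loss."""

    exit_code = 10


class MetricUndefinedError(DeepspectraError):
    """A figure of merit is undefined for the given inputs (e.g. zero SST)."""

    exit_code = 11
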