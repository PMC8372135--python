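"""Exception hierarchy for the screening pipeline.

Every error raised on bad scientific input (as opposed to programming
mistakes) derives from :class:`EvooScreenError` so callers — in particular
the CLI — can distinguish data problems from bugs.
"""


class EvooScreenError(Exception):
    """Base class for all domain errors."""


class ConfigError(EvooScreenError):
    """Invalid study design, grid or scenario configuration."""


class DataError(EvooScreenError):
    """Invalid measured or simulated data."""


class GridMismatchError(DataError):
    """Spectra that must share a wavelength grid do not."""


class DegenerateReferenceError(DataError):
    """White minus dark reference falls below the positive floor."""


class EmptyTrimError(DataError):
    """Trimming retained zero wavelength points."""


class EmptyMeasurementError(DataError):
    """All scans of a measurement were discarded."""


class SchemaError(DataError):
    """Malformed dataset file; carries the offending row where known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ZeroVarianceError(DataError):
    """SNV applied to a constant spectrum."""


class ConditioningError(DataError):
    """A covariance or kernel matrix is numerically singular."""


class SplitError(ConfigError):
    """A grouped train/test split would leave one side empty."""


class SelectionError(ConfigError):
    """Not enough candidate models to satisfy a sensor quota."""


class ScenarioError(ConfigError):
    """Scenario tuning is impossible on the given calibration set."""
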