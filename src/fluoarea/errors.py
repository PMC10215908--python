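"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: parse/data problems -> 3,
out-of-range requests -> 4, everything else -> 1.
"""


class FluoAreaError(Exception):
    """Base class for all package errors."""


class ImageFormatError(FluoAreaError):
    """Unsupported or malformed raster input (e.g. alpha channel present)."""


class TableParseError(FluoAreaError):
    """Malformed calibration/sensitivity table; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class CalibrationRangeError(FluoAreaError):
    """Requested distance outside the calibrated range."""


class FitError(FluoAreaError):
    """Least-squares fit impossible (too few points / zero variance)."""


class SceneError(FluoAreaError):
    """Invalid synthetic scene (overlapping or out-of-frame shapes)."""
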