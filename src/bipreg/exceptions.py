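"""Exception hierarchy shared across the package."""


class BipregError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(BipregError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(BipregError):
    """A geometric construction is undefined (point in the principal
    plane, parallel rays, point at the perspective center, ...)."""


class InsufficientObservationsError(BipregError):
    """Fewer observations than unknowns in a least-squares problem."""


class RankDeficiencyError(BipregError):
    """Normal matrix is singular; carries the approximate null direction."""

    def __init__(self, message, null_direction=None):
        super().__init__(message)
        self.null_direction = null_direction


class DegenerateDataError(BipregError):
    """Data left after filtering are unusable (e.g. all pairs rejected)."""


class EllipseFitError(BipregError):
    """Conic fit failed or input points are degenerate."""


class InitializationError(BipregError):
    """Coarse pose search failed; carries per-start RMSE values."""

    def __init__(self, message, rms_per_start=None):
        super().__init__(message)
        self.rms_per_start = rms_per_start


class CalibrationFormatError(BipregError, ValueError):
    """Calibration or data file is malformed; message names file and field."""


class ImplausibleScaleWarning(UserWarning):
    """Estimated scale factor drifted outside the plausible range."""
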