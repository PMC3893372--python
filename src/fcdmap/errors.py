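"""Exception hierarchy for the fcdmap pipeline."""


class FcdmapError(Exception):
    """Base class for all fcdmap errors."""


class InvalidGeometryError(FcdmapError):
    """Contours are degenerate, self-intersecting, or cross each other."""


class EmptyRibbonError(FcdmapError):
    """Rasterized grey-matter interior is empty."""


class SolverFailureError(FcdmapError):
    """Laplace solve did not reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateGradientError(FcdmapError):
    """Field-line tracing hit a region where |grad phi| is below the floor."""


class NoMidlineError(FcdmapError):
    """The phi = 0 level set is empty (degenerate ribbon)."""


class InsufficientCurveError(FcdmapError):
    """Too few points to estimate curvature."""


class UndefinedMedcoupleError(FcdmapError):
    """Medcouple is undefined (constant sample)."""


class InsufficientSampleError(FcdmapError):
    """Sample size below the configured floor for fence estimation."""


class LandmarkError(FcdmapError):
    """Stereotaxic landmark missing or out of order."""


class SaturatedMaskError(FcdmapError):
    """Foreground fraction is 1; Boolean model inversion impossible."""


class InfeasibleFitError(FcdmapError):
    """Boolean model inversion produced a non-positive intensity."""

    def __init__(self, message: str, sparse_limit_lambda: float | None = None):
        super().__init__(message)
        self.sparse_limit_lambda = sparse_limit_lambda


class WindowTooSmallError(FcdmapError):
    """Observation window smaller than twice the edge margin."""


class InvalidSizesError(FcdmapError):
    """Granulometry size list is not strictly increasing from zero."""


class UndefinedCoefficientError(FcdmapError):
    """Agreement coefficient undefined (chance agreement equals 1)."""


class PairingError(FcdmapError):
    """Cohort table contains unpaired rows."""
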