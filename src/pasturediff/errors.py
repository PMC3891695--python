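"""Exception hierarchy.

Every precondition violation raises a distinct class so callers (and the
CLI) can map failures to actionable messages without string matching.
"""


class PastureDiffError(Exception):
    """Base class for all package errors."""


class RasterError(PastureDiffError):
    """Problems with raster inputs or geotransforms."""


class BandCountError(RasterError):
    """Raster does not carry the required number of bands."""


class NonSquarePixelError(RasterError):
    """Raster pixels are not square; the pipeline assumes one pixel size."""


class NoOverlapError(RasterError):
    """Two rasters share no map-extent intersection."""


class LatticeMismatchError(RasterError):
    """Raster grids have different pixel sizes or misaligned origins."""


class RegistrationError(PastureDiffError):
    """Problems fitting or applying the image-to-image registration."""


class DegenerateTiePointsError(RegistrationError):
    """Tie points are too few, collinear, or duplicated."""


class PCAError(PastureDiffError):
    """Principal component analysis cannot be computed."""


class ConstantImageError(PCAError):
    """All bands are constant: the covariance matrix is zero."""


class ThresholdError(PastureDiffError):
    """Invalid spectral or spatial threshold configuration."""


class EmptySampleError(ThresholdError):
    """No valid difference values available to derive a threshold from."""


class EvaluationError(PastureDiffError):
    """Inconsistent counts or truth data during accuracy evaluation."""


class PlacementError(PastureDiffError):
    """Synthetic animals cannot be placed inside the scene extent."""
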