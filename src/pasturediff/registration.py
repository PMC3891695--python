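"""Tie-point affine registration, raster warping, and mis-registration assessment.

The image-to-image registration links the T1 acquisition to the T2
acquisition of the same pasture through manually identified tie points
(features visible in both frames). A first-order (6-parameter) affine
model is fitted by least squares; its root-mean-square residual is
reported in pixels, the unit in which registration quality is
conventionally quoted for airborne frame imagery.

Residual mis-registration after warping is the dominant source of false
animal detections: a sub-meter shift differences every static edge in the
scene. :func:`assess_misregistration` quantifies it from independent check
features, reporting mean and standard deviation of the absolute per-axis
offsets — directly comparable to animal body length.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateTiePointsError, RegistrationError
from .raster import GeoTransform, MultibandImage

DEFAULT_PIXEL_SIZE = 0.25


@dataclass(frozen=True)
class TiePointSet:
    """Paired map coordinates (meters): source features and their positions
    in the destination image. At least 3 non-collinear pairs are required
    to determine an affine transform."""

    source: np.ndarray  # (n, 2)
    dest: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.source, dtype=float))
        dst = np.atleast_2d(np.asarray(self.dest, dtype=float))
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "dest", dst)
        if src.shape != dst.shape or src.shape[1] != 2:
            raise DegenerateTiePointsError(
                f"tie point arrays must both be (n, 2); got {src.shape} and {dst.shape}"
            )
        if len(src) < 3:
            raise DegenerateTiePointsError(f"need >= 3 tie points, got {len(src)}")

    def __len__(self) -> int:
        return len(self.source)

    @classmethod
    def from_csv(cls, path) -> "TiePointSet":
        """Read tie points from a CSV with columns x1,y1,x2,y2 (map meters)."""
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(
                    [float(rec["x1"]), float(rec["y1"]), float(rec["x2"]), float(rec["y2"])]
                )
        arr = np.asarray(rows, dtype=float)
        if arr.size == 0:
            raise DegenerateTiePointsError(f"{path}: no tie points")
        return cls(source=arr[:, :2], dest=arr[:, 2:])


@dataclass(frozen=True)
class AffineFit:
    """Fitted 6-parameter transform  x' = a x + b y + c,  y' = d x + e y + f.

    ``rmse_pixels`` is sqrt(mean(dx^2 + dy^2)) over the tie points divided
    by the pixel size; ``residuals`` holds the per-point (dx, dy) in meters.
    """

    coefficients: np.ndarray  # (6,) = (a, b, c, d, e, f)
    rmse_pixels: float
    residuals: np.ndarray  # (n, 2) meters
    pixel_size: float

    @classmethod
    def identity(cls, pixel_size: float = DEFAULT_PIXEL_SIZE) -> "AffineFit":
        return cls(
            coefficients=np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0]),
            rmse_pixels=0.0,
            residuals=np.zeros((0, 2)),
            pixel_size=pixel_size,
        )

    @classmethod
    def translation(cls, dx: float, dy: float, pixel_size: float = DEFAULT_PIXEL_SIZE) -> "AffineFit":
        return cls(
            coefficients=np.array([1.0, 0.0, dx, 0.0, 1.0, dy]),
            rmse_pixels=0.0,
            residuals=np.zeros((0, 2)),
            pixel_size=pixel_size,
        )

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Transform (n, 2) source map coordinates to destination space."""
        a, b, c, d, e, f = self.coefficients
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return np.column_stack([a * xy[:, 0] + b * xy[:, 1] + c, d * xy[:, 0] + e * xy[:, 1] + f])

    def inverse_apply(self, xy: np.ndarray) -> np.ndarray:
        """Transform destination coordinates back to source space."""
        a, b, c, d, e, f = self.coefficients
        m = np.array([[a, b], [d, e]])
        det = np.linalg.det(m)
        if abs(det) < 1e-15:
            raise RegistrationError("affine transform is singular")
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (xy - np.array([c, f])) @ np.linalg.inv(m).T


def fit_affine(tp: TiePointSet, pixel_size: float = DEFAULT_PIXEL_SIZE) -> AffineFit:
    """Least-squares affine fit of destination on source coordinates.

    Raises :class:`DegenerateTiePointsError` if the source configuration is
    collinear or duplicated (design matrix rank < 3).
    """
    n = len(tp)
    design = np.column_stack([tp.source, np.ones(n)])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max())) < 3:
        raise DegenerateTiePointsError("source tie points are collinear or duplicated")
    sol_x, *_ = np.linalg.lstsq(design, tp.dest[:, 0], rcond=None)
    sol_y, *_ = np.linalg.lstsq(design, tp.dest[:, 1], rcond=None)
    coeff = np.concatenate([sol_x, sol_y])
    predicted = design @ np.column_stack([sol_x, sol_y])
    residuals = tp.dest - predicted
    rmse_m = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return AffineFit(
        coefficients=coeff,
        rmse_pixels=rmse_m / pixel_size,
        residuals=residuals,
        pixel_size=pixel_size,
    )


def warp(
    img: MultibandImage,
    fit: AffineFit,
    target_transform: GeoTransform,
    target_shape: tuple[int, int],
) -> MultibandImage:
    """Resample ``img`` onto the target grid under the fitted transform.

    ``fit`` maps source map coordinates into the destination (target)
    frame; each target pixel center is pulled back through the inverse
    transform and the bands are sampled bilinearly. Any output pixel whose
    bilinear 4-neighborhood touches nodata (or falls outside the source
    grid) is masked.
    """
    n_rows, n_cols = target_shape
    s = target_transform.pixel_size
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x = target_transform.origin_x + (cols + 0.5) * s
    y = target_transform.origin_y - (rows + 0.5) * s
    src_xy = fit.inverse_apply(np.column_stack([x.ravel(), y.ravel()]))

    ts = img.transform
    src_col = (src_xy[:, 0] - ts.origin_x) / ts.pixel_size - 0.5
    src_row = (ts.origin_y - src_xy[:, 1]) / ts.pixel_size - 0.5
    coords = np.vstack([src_row, src_col])

    out = np.empty((img.bands.shape[0], n_rows, n_cols))
    clean = np.where(img.mask, 0.0, img.bands)
    for i in range(img.bands.shape[0]):
        out[i] = ndimage.map_coordinates(
            clean[i], coords, order=1, mode="constant", cval=0.0
        ).reshape(n_rows, n_cols)
    # bilinear weight of invalid neighbors; >0 means the stencil touched nodata
    bad = ndimage.map_coordinates(
        img.mask.astype(float), coords, order=1, mode="constant", cval=1.0
    ).reshape(n_rows, n_cols)
    out_mask = bad > 1e-12
    inside = (
        (src_row >= 0)
        & (src_row <= img.n_rows - 1)
        & (src_col >= 0)
        & (src_col <= img.n_cols - 1)
    ).reshape(n_rows, n_cols)
    out_mask |= ~inside
    out[:, out_mask] = 0.0
    return MultibandImage(
        bands=out, transform=target_transform, mask=out_mask, band_names=img.band_names
    )


@dataclass(frozen=True)
class MisregistrationReport:
    """Absolute per-axis offsets (meters) of k check features between the
    two acquisitions, with their arithmetic means and sample standard
    deviations (n-1). With a single feature the SDs are reported absent."""

    abs_dx: np.ndarray
    abs_dy: np.ndarray
    mean_x: float
    std_x: float | None
    mean_y: float
    std_y: float | None

    @property
    def k(self) -> int:
        return len(self.abs_dx)

    def to_csv(self, path, unit: str = "m") -> None:
        """Write the report; ``unit`` is ``"m"`` or ``"cm"``."""
        if unit not in ("m", "cm"):
            raise ValueError(f"unit must be 'm' or 'cm', got {unit!r}")
        f = 100.0 if unit == "cm" else 1.0
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([f"Mean X ({unit})", f"STD X ({unit})", f"Mean Y ({unit})", f"STD Y ({unit})"])
            w.writerow(
                [
                    f * self.mean_x,
                    "" if self.std_x is None else f * self.std_x,
                    f * self.mean_y,
                    "" if self.std_y is None else f * self.std_y,
                ]
            )


def assess_misregistration(points_t1, points_t2) -> MisregistrationReport:
    """Per-axis absolute offsets between paired check features.

    The check features must be distinct from the tie points used to fit
    the registration; what remains after warping is the residual
    mis-registration that the difference image will see.
    """
    p1 = np.atleast_2d(np.asarray(points_t1, dtype=float))
    p2 = np.atleast_2d(np.asarray(points_t2, dtype=float))
    if p1.shape != p2.shape or p1.shape[1] != 2:
        raise RegistrationError(
            f"check point lists must be equal-length (k, 2); got {p1.shape} and {p2.shape}"
        )
    if len(p1) == 0:
        raise RegistrationError("need at least one check feature")
    abs_d = np.abs(p2 - p1)
    k = len(p1)
    return MisregistrationReport(
        abs_dx=abs_d[:, 0],
        abs_dy=abs_d[:, 1],
        mean_x=float(abs_d[:, 0].mean()),
        std_x=float(abs_d[:, 0].std(ddof=1)) if k > 1 else None,
        mean_y=float(abs_d[:, 1].mean()),
        std_y=float(abs_d[:, 1].std(ddof=1)) if k > 1 else None,
    )
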