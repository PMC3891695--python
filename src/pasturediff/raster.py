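"""Raster data model and GeoTIFF I/O.

Conventions used throughout the package:

* planar map coordinates in meters (UTM-like), north-up grids;
* 0-based (row, col) pixel indices, row index grows southward;
* point coordinates refer to pixel CENTERS;
* pixel footprints are half-open: ``[x, x + s) x (y - s, y]`` so a point on
  a shared edge belongs to exactly one pixel (the higher column / the
  higher-index, i.e. more southerly, row);
* nodata is carried as a boolean mask, never as a sentinel value, so that
  downstream arithmetic (PCA, differencing) cannot ingest fill values.

GeoTIFF files are written with the standard ModelPixelScale, ModelTiepoint
and GDAL_NODATA tags and a minimal GeoKey directory, so they round-trip
through this module and open in common GIS software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import (
    BandCountError,
    LatticeMismatchError,
    NonSquarePixelError,
    NoOverlapError,
    RasterError,
)

DEFAULT_BAND_NAMES = ("green", "red", "nir")
_NODATA_SENTINEL = -9999.0

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

#: minimal GeoKey directory: projected model, pixel-is-area raster space
_GEO_KEYS = (1, 1, 0, 2, 1024, 0, 1, 1, 1025, 0, 1, 1)

_LATTICE_TOL = 1e-6  # meters


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine geotransform with square pixels.

    Parameters
    ----------
    origin_x, origin_y : float
        Map coordinates (meters) of the OUTER top-left corner of pixel
        (0, 0).
    pixel_size : float
        Edge length of a pixel in meters (0.25 for the airborne system
        this package targets).
    """

    origin_x: float
    origin_y: float
    pixel_size: float

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise NonSquarePixelError(f"pixel_size must be > 0, got {self.pixel_size}")

    def pixel_to_map(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the CENTER of pixel (row, col)."""
        s = self.pixel_size
        return (self.origin_x + (col + 0.5) * s, self.origin_y - (row + 0.5) * s)

    def map_to_pixel(self, x: float, y: float) -> tuple[int, int]:
        """Pixel (row, col) whose half-open footprint contains (x, y).

        A point exactly on a vertical edge belongs to the pixel on its
        right (higher col); a point on a horizontal edge belongs to the
        pixel below it in map terms (higher row index).
        """
        s = self.pixel_size
        col = math.floor((x - self.origin_x) / s)
        row = math.floor((self.origin_y - y) / s)
        return (row, col)


@dataclass
class MultibandImage:
    """A 3-band reflectance grid with geotransform and nodata mask.

    ``bands`` has shape (3, n_rows, n_cols); ``mask`` is True where a
    pixel is invalid in ANY band.
    """

    bands: np.ndarray
    transform: GeoTransform
    mask: np.ndarray = None  # type: ignore[assignment]
    band_names: tuple[str, ...] = DEFAULT_BAND_NAMES

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        if self.bands.ndim != 3:
            raise BandCountError(
                f"bands must be a (n_bands, rows, cols) array, got shape {self.bands.shape}"
            )
        if self.bands.shape[0] != len(self.band_names):
            raise BandCountError(
                f"band count {self.bands.shape[0]} does not match "
                f"band names {self.band_names}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.bands.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.bands.shape[1:]:
            raise RasterError(
                f"mask shape {self.mask.shape} does not match grid {self.bands.shape[1:]}"
            )
        # fold NaNs into the mask so arithmetic never sees them silently
        self.mask |= np.isnan(self.bands).any(axis=0)
        if self.mask.all():
            raise RasterError("image has no valid pixels")

    @property
    def n_rows(self) -> int:
        return self.bands.shape[1]

    @property
    def n_cols(self) -> int:
        return self.bands.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the grid footprint in meters."""
        t = self.transform
        s = t.pixel_size
        return (
            t.origin_x,
            t.origin_y - self.n_rows * s,
            t.origin_x + self.n_cols * s,
            t.origin_y,
        )

    def band(self, name: str) -> np.ndarray:
        return self.bands[self.band_names.index(name)]


def write_geotiff(img: MultibandImage, path) -> None:
    """Write a MultibandImage as a float32 GeoTIFF with a nodata tag.

    Masked pixels are stored as the nodata sentinel; identical inputs
    produce byte-identical files (fixed creation options, no timestamps).
    """
    data = img.bands.astype(np.float32)
    data = np.where(img.mask[None, :, :], np.float32(_NODATA_SENTINEL), data)
    t = img.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.pixel_size, t.pixel_size, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.origin_x, t.origin_y, 0.0), True),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS, True),
        (_TAG_GDAL_NODATA, "s", 0, str(_NODATA_SENTINEL), True),
    ]
    kwargs = {}
    if data.shape[0] == 1:
        data = data[0]  # single-band rasters are plain 2-D grayscale pages
    else:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        metadata=None,
        extratags=extratags,
        software="pasturediff",
        **kwargs,
    )


def read_geotiff(path, band_names: tuple[str, ...] = DEFAULT_BAND_NAMES) -> MultibandImage:
    """Read a >=3-band GeoTIFF into a MultibandImage.

    The first ``len(band_names)`` file bands are taken in order (default
    green/red/nir); pass a different ``band_names`` tuple to relabel or,
    for single-band rasters, read with ``band_names=("value",)``.
    """
    try:
        tif = tifffile.TiffFile(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"raster not found: {path}") from None
    with tif:
        page = tif.pages[0]
        data = tif.asarray()
        if data.ndim == 2:
            data = data[None, :, :]
        elif data.ndim == 3 and data.shape[0] not in (1, 2, 3, 4) and data.shape[2] <= 4:
            data = np.moveaxis(data, -1, 0)  # interleaved layout
        if data.shape[0] < len(band_names):
            raise BandCountError(
                f"{path}: expected >= {len(band_names)} bands, found {data.shape[0]}"
            )
        data = data[: len(band_names)].astype(np.float64)

        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=0, abs_tol=_LATTICE_TOL):
            raise NonSquarePixelError(f"{path}: non-square pixels ({sx} x {sy})")
        tp = tags[_TAG_MODEL_TIEPOINT].value
        # tiepoint: raster (i, j, k) -> model (x, y, z); anchor at pixel (0,0)
        origin_x = tp[3] - tp[0] * sx
        origin_y = tp[4] + tp[1] * sy
        transform = GeoTransform(origin_x, origin_y, float(sx))

        mask = np.zeros(data.shape[1:], dtype=bool)
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
            mask |= np.isclose(data, nodata, rtol=0, atol=1e-3).any(axis=0)
        mask |= np.isnan(data).any(axis=0)
        data = np.where(mask[None, :, :], 0.0, data)

    return MultibandImage(bands=data, transform=transform, mask=mask, band_names=band_names)


def clip_to_common_extent(
    a: MultibandImage, b: MultibandImage
) -> tuple[MultibandImage, MultibandImage]:
    """Clip two lattice-aligned images to the intersection of their footprints.

    Both inputs must share the pixel size and sit on a common lattice
    (origins differing by integer pixel multiples within 1e-6 m). The two
    outputs share an identical GeoTransform and shape.
    """
    ta, tb = a.transform, b.transform
    s = ta.pixel_size
    if abs(s - tb.pixel_size) > _LATTICE_TOL:
        raise LatticeMismatchError(
            f"pixel sizes differ: {s} vs {tb.pixel_size}"
        )
    for da in ((tb.origin_x - ta.origin_x) / s, (tb.origin_y - ta.origin_y) / s):
        if abs(da - round(da)) * s > _LATTICE_TOL:
            raise LatticeMismatchError(
                "grids are not aligned to a common lattice "
                f"(origin offset {da} pixels)"
            )

    ax0, ay0, ax1, ay1 = a.extent()
    bx0, by0, bx1, by1 = b.extent()
    x0, x1 = max(ax0, bx0), min(ax1, bx1)
    y0, y1 = max(ay0, by0), min(ay1, by1)
    if x1 - x0 < s / 2 or y1 - y0 < s / 2:
        raise NoOverlapError("image extents have no overlap")

    def _window(img: MultibandImage) -> MultibandImage:
        t = img.transform
        c0 = round((x0 - t.origin_x) / s)
        r0 = round((t.origin_y - y1) / s)
        n_cols = round((x1 - x0) / s)
        n_rows = round((y1 - y0) / s)
        return MultibandImage(
            bands=img.bands[:, r0 : r0 + n_rows, c0 : c0 + n_cols].copy(),
            transform=GeoTransform(x0, y1, s),
            mask=img.mask[r0 : r0 + n_rows, c0 : c0 + n_cols].copy(),
            band_names=img.band_names,
        )

    return _window(a), _window(b)
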