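"""Spectral thresholding, polygonization, and the area (spatial) filter.

Pixels whose absolute PC1 difference falls inside the spectral threshold
interval are classed as change; 8-connected groups of change pixels are
converted to polygons whose boundaries trace the exact pixel edges (no
smoothing or simplification, so size and shape are preserved); polygons
outside the admissible animal-area interval — by default 0.99 to 10 m²,
the lower bound rejecting point-spread speckle and the upper bound
rejecting features too large even for two adjacent animals — are removed.
Whatever survives is a candidate animal.

The lower spectral threshold is the step the original workflow left to
human interpretation. :func:`suggest_threshold` makes it reproducible:
it samples the difference values in a small window around each known
animal position and takes a low percentile, so (almost) every animal
window sits at or above the returned value. The percentile is an explicit
parameter and a manually chosen threshold can always be supplied instead —
hence "semi-automated".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import ndimage
from shapely.geometry import box, mapping, shape as shapely_shape
from shapely.ops import unary_union

from .errors import EmptySampleError, ThresholdError
from .pca import DifferenceImage
from .raster import GeoTransform


@dataclass(frozen=True)
class SpectralThreshold:
    """Closed interval [t_low, t_high] of absolute PC1 difference classed
    as change; t_high defaults to +inf (one-sided threshold)."""

    t_low: float
    t_high: float = math.inf

    def __post_init__(self) -> None:
        if not (0 <= self.t_low < self.t_high):
            raise ThresholdError(
                f"need 0 <= t_low < t_high, got [{self.t_low}, {self.t_high}]"
            )


@dataclass(frozen=True)
class SpatialThreshold:
    """Admissible polygon area interval in m²; inclusive at both ends.

    The published removal rules are strict ("> 10 m² too large",
    "< 0.99 m² too small"), so areas exactly on a bound are kept.
    """

    min_area: float = 0.99
    max_area: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ThresholdError(
                f"need 0 < min_area < max_area, got [{self.min_area}, {self.max_area}]"
            )


def threshold_mask(diff: DifferenceImage, st: SpectralThreshold) -> np.ndarray:
    """Boolean change mask: unmasked and t_low <= value <= t_high."""
    return ~diff.mask & (diff.values >= st.t_low) & (diff.values <= st.t_high)


def suggest_threshold(
    diff: DifferenceImage,
    truth,
    percentile: float = 0.05,
    window: int = 3,
) -> SpectralThreshold:
    """Derive t_low from the difference values at known animal positions.

    Samples an odd ``window`` x ``window`` pixel neighborhood around each
    animal's T1 and T2 position and returns the given percentile (a
    fraction in [0, 1]) of the pooled values as t_low, with t_high = +inf.
    """
    if not 0 <= percentile <= 1:
        raise ThresholdError(f"percentile must be a fraction in [0, 1], got {percentile}")
    if window < 1 or window % 2 == 0:
        raise ThresholdError(f"window must be odd and >= 1, got {window}")
    half = window // 2
    n_rows, n_cols = diff.shape
    samples: list[np.ndarray] = []
    for animal in truth.animals:
        for pos in (animal.pos_t1, animal.pos_t2):
            row, col = diff.transform.map_to_pixel(*pos)
            r0, r1 = max(0, row - half), min(n_rows, row + half + 1)
            c0, c1 = max(0, col - half), min(n_cols, col + half + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            win = diff.values[r0:r1, c0:c1]
            ok = ~diff.mask[r0:r1, c0:c1]
            if ok.any():
                samples.append(win[ok])
    if not samples:
        raise EmptySampleError("no valid difference values around any truth position")
    pooled = np.concatenate(samples)
    return SpectralThreshold(t_low=float(np.quantile(pooled, percentile)))


@dataclass
class DetectionPolygon:
    """One 8-connected clump of change pixels: a candidate animal.

    ``pixels`` is an (n, 2) array of (row, col); the boundary traces exact
    pixel edges and is built lazily from the pixel footprints. The area is
    an exact multiple of pixel_size² and the centroid is the mean of the
    member pixel centers.
    """

    pixels: np.ndarray
    transform: GeoTransform
    _geometry: object = field(default=None, repr=False)

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)

    @property
    def area_m2(self) -> float:
        return self.pixel_count * self.transform.pixel_size**2

    @property
    def centroid(self) -> tuple[float, float]:
        centers = np.array(
            [self.transform.pixel_to_map(int(r), int(c)) for r, c in self.pixels]
        )
        return (float(centers[:, 0].mean()), float(centers[:, 1].mean()))

    @cached_property
    def geometry(self):
        """Shapely polygon union of the member pixel footprints (unsmoothed)."""
        if self._geometry is not None:
            return self._geometry
        t = self.transform
        s = t.pixel_size
        cells = [
            box(
                t.origin_x + c * s,
                t.origin_y - (r + 1) * s,
                t.origin_x + (c + 1) * s,
                t.origin_y - r * s,
            )
            for r, c in self.pixels
        ]
        return unary_union(cells)


def extract_polygons(
    mask: np.ndarray, transform: GeoTransform, connectivity: int = 8
) -> list[DetectionPolygon]:
    """One polygon per connected component of True cells.

    ``connectivity`` is 8 (default: diagonal neighbors join, matching the
    compact-blob-with-halo structure of animal change footprints) or 4.
    Components are returned sorted by (min row, min col) for determinism.
    """
    if connectivity not in (4, 8):
        raise ThresholdError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    if n == 0:
        return []
    order = []
    for lbl, sl in enumerate(ndimage.find_objects(labels), start=1):
        rr, cc = np.nonzero(labels[sl] == lbl)
        pixels = np.column_stack([rr + sl[0].start, cc + sl[1].start])
        order.append(((pixels[:, 0].min(), pixels[:, 1].min()), pixels))
    order.sort(key=lambda item: (int(item[0][0]), int(item[0][1])))
    return [DetectionPolygon(pixels=p, transform=transform) for _, p in order]


def filter_by_area(
    polys: list[DetectionPolygon], st: SpatialThreshold = SpatialThreshold()
) -> list[DetectionPolygon]:
    """Keep polygons with min_area <= area <= max_area; order preserved."""
    return [p for p in polys if st.min_area <= p.area_m2 <= st.max_area]


def write_polygons_geojson(polys, path) -> None:
    """Write detections as a GeoJSON FeatureCollection (map coordinates)."""
    features = []
    for i, p in enumerate(polys):
        cx, cy = p.centroid
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(p.geometry),
                "properties": {
                    "id": i,
                    "area_m2": p.area_m2,
                    "pixel_count": p.pixel_count,
                    "centroid_x": cx,
                    "centroid_y": cy,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)


@dataclass
class LoadedPolygon:
    """A detection re-read from GeoJSON: geometry plus the stored area."""

    geometry: object
    area_m2: float
    pixel_count: int
    centroid: tuple[float, float]


def read_polygons_geojson(path) -> list[LoadedPolygon]:
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc.get("features", []):
        geom = shapely_shape(feat["geometry"])
        props = feat.get("properties", {})
        out.append(
            LoadedPolygon(
                geometry=geom,
                area_m2=float(props.get("area_m2", geom.area)),
                pixel_count=int(props.get("pixel_count", 0)),
                centroid=(
                    float(props.get("centroid_x", geom.centroid.x)),
                    float(props.get("centroid_y", geom.centroid.y)),
                ),
            )
        )
    return out
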