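"""Per-image principal component analysis and PC1 differencing.

The three reflectance bands of a grassland scene are strongly correlated;
the first principal component of their covariance matrix concentrates the
shared brightness signal, so one PC1 layer per acquisition captures most
of the scene structure in a single band. Differencing the two PC1 layers
pixel-by-pixel and taking absolute values yields a change magnitude image:
near zero where the scene is static, large where an animal occupied a
pixel in one acquisition but not the other.

Two numerical details matter:

* PCA is computed per image over its valid pixels only, from the 3x3
  COVARIANCE matrix (bands share one physical unit, so no rescaling).
* The sign of an eigenvector is arbitrary. An uncontrolled flip between
  the two acquisitions would turn "no change" into "maximal change", so
  the sign is fixed deterministically: the sum of the three loadings is
  made positive (if the sum is zero, the first nonzero loading is made
  positive). PC1 of two near-identical images is then near-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConstantImageError, PCAError
from .raster import GeoTransform, MultibandImage, clip_to_common_extent

_SIGN_TOL = 1e-12


@dataclass
class PCAResult:
    """Eigen-decomposition of an image's band covariance plus its PC1 grid.

    ``eigenvectors`` holds components in COLUMNS, eigenvalues sorted
    descending; ``pc1`` is the centered band vector of each valid pixel
    projected on the leading eigenvector (masked pixels are NaN).
    """

    eigenvalues: np.ndarray  # (3,) descending
    eigenvectors: np.ndarray  # (3, 3), columns orthonormal
    variance_fraction: np.ndarray  # (3,), sums to 1
    pc1: np.ndarray  # (rows, cols), NaN where masked
    mask: np.ndarray
    transform: GeoTransform

    def to_json(self, path=None) -> str:
        payload = {
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.eigenvectors.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _fix_sign(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if abs(s) < _SIGN_TOL:
        nz = np.flatnonzero(np.abs(v) > _SIGN_TOL)
        s = v[nz[0]] if len(nz) else 1.0
    return -v if s < 0 else v


def compute_pca(img: MultibandImage) -> PCAResult:
    """Principal component analysis of the band covariance over valid pixels."""
    valid = ~img.mask
    n_valid = int(valid.sum())
    if n_valid < 4:
        raise PCAError(f"need >= 4 valid pixels for a covariance estimate, got {n_valid}")
    x = img.bands[:, valid].T  # (n, 3)
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    total = float(np.trace(cov))
    # round-off floor: centering a constant image leaves O(eps^2) variance
    floor = (1e-12 * max(1.0, float(np.abs(x).max()))) ** 2
    if total <= floor or not np.isfinite(total):
        raise ConstantImageError("all bands are constant; covariance matrix is zero")

    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for i in range(evecs.shape[1]):
        evecs[:, i] = _fix_sign(evecs[:, i])

    pc1 = np.full(img.shape, np.nan)
    pc1[valid] = (x - mu) @ evecs[:, 0]
    return PCAResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        variance_fraction=evals / evals.sum(),
        pc1=pc1,
        mask=img.mask.copy(),
        transform=img.transform,
    )


@dataclass
class DifferenceImage:
    """Absolute PC1 difference |PC1(T2) - PC1(T1)| on the clipped common
    grid, with the union of the two input masks."""

    values: np.ndarray
    transform: GeoTransform
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise PCAError("difference values and mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def write_geotiff(self, path) -> None:
        from .raster import write_geotiff

        img = MultibandImage(
            bands=np.where(self.mask, 0.0, self.values)[None, :, :],
            transform=self.transform,
            mask=self.mask,
            band_names=("pc1_absdiff",),
        )
        write_geotiff(img, path)

    @classmethod
    def read_geotiff(cls, path) -> "DifferenceImage":
        from .raster import read_geotiff

        img = read_geotiff(path, band_names=("pc1_absdiff",))
        return cls(values=img.bands[0], transform=img.transform, mask=img.mask)


def difference_pc1(
    t1: MultibandImage, t2: MultibandImage
) -> tuple[DifferenceImage, PCAResult, PCAResult]:
    """Clip both acquisitions to their common extent, run an independent
    PCA on each clipped image, and return the absolute PC1 difference.

    Clipping precedes the decompositions so both see the same spatial
    support; the result is symmetric under argument swap and invariant to
    adding a constant to all bands of either image.
    """
    c1, c2 = clip_to_common_extent(t1, t2)
    p1 = compute_pca(c1)
    p2 = compute_pca(c2)
    union_mask = p1.mask | p2.mask
    values = np.abs(np.where(union_mask, 0.0, p2.pc1) - np.where(union_mask, 0.0, p1.pc1))
    values[union_mask] = 0.0
    diff = DifferenceImage(values=values, transform=c1.transform, mask=union_mask)
    return diff, p1, p2
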