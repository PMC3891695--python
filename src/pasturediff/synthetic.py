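"""Synthetic paired pasture scenes with known animal locations.

The generator emulates the statistical structure the differencing method
assumes: a grassland background whose reflectance varies smoothly (a
spatially correlated random field), sparse static bare-soil patches with
strong NIR contrast (the "mixture of dense and sparse grasslands" of real
pastures — their sharp edges are what mis-registration turns into false
change), compact animal-sized ellipses that move several meters between
the two acquisitions, optional attached shadows whose offset differs
between acquisitions as the sun moves, an optional global sub-2 m
mis-registration applied to T2 by resampling, a point-spread blur, and
additive per-acquisition sensor noise.

Default reflectances are plausible for autumn grassland at green/red/NIR:
background (0.08, 0.10, 0.30), dark animals at (-0.03, -0.04, -0.15)
offsets, bare soil at (+0.02, +0.02, -0.15). Everything is reproducible
from a single integer seed; a multi-pasture suite derives per-scene seeds
as ``base_seed + index``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .errors import PlacementError
from .evaluate import Animal, TruthSet
from .raster import GeoTransform, MultibandImage, write_geotiff

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class ShadowConfig:
    """Attached animal shadows: offset of the shadow ellipse from the body
    center at each acquisition (meters, sun-dependent) and the multiplicative
    intensity applied inside the shadow (< 1 darkens)."""

    enabled: bool = False
    offset_t1: tuple[float, float] = (1.8, -2.2)
    offset_t2: tuple[float, float] = (2.6, -3.0)
    intensity: float = 0.6


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic pasture and its two acquisitions."""

    extent: tuple[float, float] = (250.0, 250.0)  # meters (x, y); ~6.2 ha
    pixel_size: float = 0.25
    n_animals: int = 10
    animal_area_range: tuple[float, float] = (1.2, 3.0)  # m2 body footprint
    animal_aspect_range: tuple[float, float] = (1.5, 2.5)
    animal_reflectance: tuple[float, float, float] = (-0.03, -0.04, -0.15)
    animal_contrast_jitter: tuple[float, float] = (0.8, 1.2)
    movement_distance: tuple[float, float] = (2.0, 20.0)  # uniform, meters
    background_mean: tuple[float, float, float] = (0.08, 0.10, 0.30)
    correlation_length: float = 2.0  # meters
    texture_sd: float = 0.01  # reflectance units, NIR band
    n_soil_patches: int = 40
    patch_area_range: tuple[float, float] = (2.0, 20.0)  # m2
    patch_reflectance: tuple[float, float, float] = (0.02, 0.02, -0.15)
    shadow: ShadowConfig = field(default_factory=ShadowConfig)
    misregistration: tuple[float, float] = (0.0, 0.0)  # (dx, dy) meters on T2
    noise_sd: float = 0.003  # additive, per band per acquisition
    psf_sigma_px: float = 0.7  # point-spread blur, pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")
        if self.noise_sd < 0 or self.texture_sd < 0:
            raise ValueError("noise/texture standard deviations must be >= 0")
        px_area = self.pixel_size**2
        if not (px_area <= self.animal_area_range[0] <= self.animal_area_range[1]):
            raise ValueError("animal areas must lie within [pixel area, extent]")

    def grid_shape(self) -> tuple[int, int]:
        return (
            int(round(self.extent[1] / self.pixel_size)),
            int(round(self.extent[0] / self.pixel_size)),
        )

    def transform(self) -> GeoTransform:
        return GeoTransform(0.0, self.extent[1], self.pixel_size)


@dataclass
class SyntheticScene:
    t1: MultibandImage
    t2: MultibandImage
    truth: TruthSet
    config: SceneConfig


def _ellipse_mask(
    shape: tuple[int, int],
    transform: GeoTransform,
    center: tuple[float, float],
    area: float,
    aspect: float,
    theta: float,
) -> np.ndarray:
    """Boolean raster of an ellipse of the given area/aspect/orientation;
    a pixel belongs if its center falls inside."""
    a = np.sqrt(area * aspect / np.pi)  # semi-major, meters
    b = np.sqrt(area / (aspect * np.pi))
    s = transform.pixel_size
    cx, cy = center
    half = a + s
    r0, c0 = transform.map_to_pixel(cx - half, cy + half)
    r1, c1 = transform.map_to_pixel(cx + half, cy - half)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1 + 1, shape[0]), min(c1 + 1, shape[1])
    mask = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    x = transform.origin_x + (cols + 0.5) * s - cx
    y = transform.origin_y - (rows + 0.5) * s - cy
    xx, yy = np.meshgrid(x, y)
    ct, st = np.cos(theta), np.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    mask[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _correlated_field(rng, shape, corr_len_px: float) -> np.ndarray:
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_len_px)
    sd = g.std()
    return g / sd if sd > 0 else g


def _shift_bands(bands: np.ndarray, dx_m: float, dy_m: float, pixel_size: float) -> np.ndarray:
    """Resample so content appears displaced by (dx, dy) map meters."""
    if dx_m == 0.0 and dy_m == 0.0:
        return bands
    # ndimage.shift: output(i) = input(i - shift). A +dx map shift is
    # +dx/s columns; +dy map shift is -dy/s rows (row grows southward).
    shift = (-dy_m / pixel_size, dx_m / pixel_size)
    out = np.empty_like(bands)
    for i in range(bands.shape[0]):
        out[i] = ndimage.shift(bands[i], shift, order=1, mode="nearest")
    return out


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Render one pasture pair (T1, T2) and its truth set from the seed."""
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.grid_shape()
    transform = cfg.transform()
    s = cfg.pixel_size
    ext_x, ext_y = cfg.extent

    # --- static background: smooth field + bare-soil patches ------------
    rel = np.asarray(cfg.background_mean) / max(cfg.background_mean)
    fld = _correlated_field(rng, shape, cfg.correlation_length / s)
    background = np.stack(
        [m + cfg.texture_sd * r * fld for m, r in zip(cfg.background_mean, rel)]
    )
    for _ in range(cfg.n_soil_patches):
        center = (rng.uniform(0, ext_x), rng.uniform(0, ext_y))
        area = rng.uniform(*cfg.patch_area_range)
        aspect = rng.uniform(1.0, 3.0)
        theta = rng.uniform(0, np.pi)
        pm = _ellipse_mask(shape, transform, center, area, aspect, theta)
        for i, off in enumerate(cfg.patch_reflectance):
            background[i][pm] += off

    # --- animal placement with rejection sampling ------------------------
    a_max = np.sqrt(cfg.animal_area_range[1] * cfg.animal_aspect_range[1] / np.pi)
    margin = a_max + 0.5
    if cfg.shadow.enabled:
        margin += max(
            np.hypot(*cfg.shadow.offset_t1), np.hypot(*cfg.shadow.offset_t2)
        ) + a_max
    if 2 * margin >= min(ext_x, ext_y):
        raise PlacementError("extent too small for the configured animal/shadow sizes")

    animals = []
    renders = []  # (pos_t1, pos_t2, area, aspect, theta, jitter)
    for k in range(cfg.n_animals):
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            p1 = (rng.uniform(margin, ext_x - margin), rng.uniform(margin, ext_y - margin))
            dist = rng.uniform(*cfg.movement_distance)
            ang = rng.uniform(0, 2 * np.pi)
            p2 = (p1[0] + dist * np.cos(ang), p1[1] + dist * np.sin(ang))
            if margin <= p2[0] <= ext_x - margin and margin <= p2[1] <= ext_y - margin:
                break
        else:
            raise PlacementError(
                f"could not place animal {k} inside the extent after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        area = rng.uniform(*cfg.animal_area_range)
        aspect = rng.uniform(*cfg.animal_aspect_range)
        theta = rng.uniform(0, np.pi)
        jitter = rng.uniform(*cfg.animal_contrast_jitter)
        animals.append(Animal(id=f"a{k:03d}", pos_t1=p1, pos_t2=p2))
        renders.append((p1, p2, area, aspect, theta, jitter))

    # --- render the two acquisitions -------------------------------------
    def _render(which: int) -> np.ndarray:
        bands = background.copy()
        shadow_off = cfg.shadow.offset_t1 if which == 1 else cfg.shadow.offset_t2
        for p1, p2, area, aspect, theta, jitter in renders:
            pos = p1 if which == 1 else p2
            if cfg.shadow.enabled:
                sc = (pos[0] + shadow_off[0], pos[1] + shadow_off[1])
                sm = _ellipse_mask(shape, transform, sc, area, aspect, theta)
                bands[:, sm] *= cfg.shadow.intensity
            am = _ellipse_mask(shape, transform, pos, area, aspect, theta)
            for i, off in enumerate(cfg.animal_reflectance):
                bands[i][am] += off * jitter
        if cfg.psf_sigma_px > 0:
            for i in range(bands.shape[0]):
                bands[i] = ndimage.gaussian_filter(bands[i], sigma=cfg.psf_sigma_px)
        return bands

    t1_bands = _render(1)
    t2_bands = _shift_bands(_render(2), *cfg.misregistration, pixel_size=s)
    if cfg.noise_sd > 0:
        t1_bands = t1_bands + rng.normal(0, cfg.noise_sd, t1_bands.shape)
        t2_bands = t2_bands + rng.normal(0, cfg.noise_sd, t2_bands.shape)

    t1 = MultibandImage(bands=t1_bands, transform=transform)
    t2 = MultibandImage(bands=t2_bands, transform=transform)
    return SyntheticScene(t1=t1, t2=t2, truth=TruthSet(animals=animals), config=cfg)


def generate_pasture_suite(
    n_pastures: int,
    base_cfg: SceneConfig = SceneConfig(),
    overrides: list[dict] | None = None,
) -> list[SyntheticScene]:
    """Independent scenes with seeds ``base_cfg.seed + index``.

    ``overrides`` is an optional per-pasture list of SceneConfig field
    replacements (e.g. ``{"n_animals": 38}``) so a suite can mirror the
    campaign's spread of herd sizes.
    """
    if n_pastures < 1:
        raise ValueError("n_pastures must be >= 1")
    if overrides is not None and len(overrides) != n_pastures:
        raise ValueError("overrides list must have one entry per pasture")
    scenes = []
    for i in range(n_pastures):
        repl = dict(overrides[i]) if overrides else {}
        repl["seed"] = base_cfg.seed + i
        scenes.append(generate_scene(dataclasses.replace(base_cfg, **repl)))
    return scenes


def write_scene(scene: SyntheticScene, outdir) -> None:
    """Materialize a scene: t1.tif, t2.tif, truth.csv, truth.geojson,
    config.yaml under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_geotiff(scene.t1, out / "t1.tif")
    write_geotiff(scene.t2, out / "t2.tif")
    scene.truth.to_csv(out / "truth.csv")
    scene.truth.to_geojson(out / "truth.geojson")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(scene.config), fh, sort_keys=False)
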