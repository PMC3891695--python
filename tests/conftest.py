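import numpy as np
import pytest

from pasturediff import GeoTransform, MultibandImage, SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def transform():
    return GeoTransform(origin_x=0.0, origin_y=100.0, pixel_size=0.25)


def make_image(rng, n_rows=10, n_cols=12, origin=(0.0, 100.0), pixel_size=0.25):
    """Small random 3-band image helper."""
    return MultibandImage(
        bands=rng.random((3, n_rows, n_cols)),
        transform=GeoTransform(origin[0], origin[1], pixel_size),
    )


@pytest.fixture
def small_image(rng):
    return make_image(rng)


def small_scene_config(seed=0, **overrides):
    """Compact pasture for fast pipeline tests: strong uniform contrast,
    few animals, 80 x 80 m."""
    fields = dict(
        seed=seed,
        extent=(80.0, 80.0),
        n_animals=5,
        animal_area_range=(2.2, 2.8),
        animal_aspect_range=(1.8, 2.2),
        animal_reflectance=(-0.05, -0.06, -0.20),
        animal_contrast_jitter=(1.0, 1.0),
        n_soil_patches=6,
        psf_sigma_px=0.5,
    )
    fields.update(overrides)
    return SceneConfig(**fields)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(small_scene_config(seed=7))
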