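import numpy as np
import pytest

from sporedetect import fit_colour_model
from sporedetect.synthetic import SceneSpec, harvest_training_pixels, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """A 1024x1024 scene with 5 spores and 20 dust distractors (seed 7)."""
    spec = SceneSpec(seed=7)
    image, truth = render_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def trained_model(default_scene):
    """Colour model trained on 3000 interior pixels of the default scene."""
    _, image, truth = default_scene
    samples = harvest_training_pixels(image, truth, 3000, seed=1)
    return fit_colour_model(samples)


@pytest.fixture(scope="session")
def small_scene():
    """A quicker 512x512 scene with 3 spores and 8 dust (seed 21)."""
    spec = SceneSpec(width_px=512, height_px=512, n_spores=3, n_dust=8, seed=21)
    image, truth = render_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_model(small_scene):
    _, image, truth = small_scene
    samples = harvest_training_pixels(image, truth, 2000, seed=2)
    return fit_colour_model(samples)
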