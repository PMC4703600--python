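import numpy as np
import pytest

from endocolor.synthetic import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gray_ramp():
    """32-row grayscale ramp covering every intensity 0..255."""
    return np.tile(np.arange(256, dtype=np.uint8), (32, 1))


@pytest.fixture
def achromatic_ramp_theme(gray_ramp):
    """RGB theme whose every pixel is achromatic: builds an identity map."""
    return np.stack([gray_ramp] * 3, axis=-1)


@pytest.fixture
def small_scene():
    """Small deterministic endoscopy-like scene for pipeline tests."""
    return generate_scene(SceneParams(height=96, width=96, vessel_count=4, seed=7))


def random_rgb(rng, h=24, w=24):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


def random_gray(rng, h=24, w=24):
    return rng.integers(0, 256, size=(h, w), dtype=np.uint8)
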