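import numpy as np
import pytest

from specseg.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One 180x180 synthetic scene with all three reflection types."""
    return generate_scene(SceneSpec(seed=3))


@pytest.fixture(scope="session")
def tiny_scene():
    """A reduced scene (one reflection of each type) for pipeline tests."""
    return generate_scene(
        SceneSpec(width=128, height=128, n_type1=1, n_type2=1, n_type3=1,
                  n_sheen=1, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_color_image(rng, shape=(32, 32), smooth=False):
    """Random uint8 RGB test image; optionally spatially smoothed."""
    img = rng.integers(0, 256, size=(*shape, 3), dtype=np.uint8)
    if smooth:
        import scipy.ndimage as ndi

        img = ndi.gaussian_filter(img.astype(float), (1.5, 1.5, 0))
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img
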