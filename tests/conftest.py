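import numpy as np
import pytest
from scipy import ndimage

from cannulascope import synth


@pytest.fixture(scope="session")
def small_spec():
    """Noise-free 128x128 scene with 12 cells."""
    return synth.SceneSpec(fov_px=(128, 128), n_cells=12, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    masks, centers = synth.make_cells(small_spec, min_separation_px=14)
    return masks, centers


@pytest.fixture(scope="session")
def textured_image():
    """Smooth random texture with correlation structure at several scales."""
    rng = np.random.default_rng(11)
    img = ndimage.gaussian_filter(rng.random((128, 128)), 1.5)
    img += 0.5 * ndimage.gaussian_filter(rng.random((128, 128)), 6)
    return img
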