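import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    from plic import SceneParams

    return SceneParams()


@pytest.fixture(scope="session")
def small_params():
    """Compact geometry for fast unit tests (not the study conditions)."""
    from plic import SceneParams

    return SceneParams(image_side=33, cell_radius=13.0)


@pytest.fixture(scope="session")
def probes_only_features(default_params):
    """Shared probes-only control feature table (expensive, session-scoped)."""
    from plic import extract_features, generate_probes_only

    cells, _ = generate_probes_only(400, default_params, seed=901)
    return extract_features(cells)


def random_blob_image(rng, side=31, integer=False):
    """Random test image: smooth blobs plus noise, nonnegative."""
    from scipy import ndimage

    img = rng.uniform(0, 1, (side, side))
    img = ndimage.gaussian_filter(img, rng.uniform(1.0, 3.0)) * 100
    img += rng.uniform(0, 20, (side, side))
    n_spots = rng.integers(0, 6)
    for _ in range(n_spots):
        r, c = rng.integers(2, side - 2, 2)
        img[r, c] += rng.uniform(50, 300)
    img = np.clip(img, 0, None)
    if integer:
        img = np.floor(img)
    return img


def random_mask(rng, side=31):
    """Random connected-ish mask: an off-centre ellipse."""
    yy, xx = np.mgrid[0:side, 0:side]
    cy, cx = rng.uniform(side * 0.3, side * 0.7, 2)
    ry, rx = rng.uniform(side * 0.15, side * 0.4, 2)
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
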