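import numpy as np
import pytest
from scipy import ndimage

from serialrecon.phantom import PhantomSpec, section_phantom


@pytest.fixture(scope="session")
def blob_image():
    """Compact tissue-like test image: smooth blob with internal texture."""
    rng = np.random.default_rng(0)
    n = 64
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    blob = np.exp(-0.5 * (np.hypot(yy - 32, xx - 32) / 12) ** 2)
    tex = ndimage.gaussian_filter(rng.standard_normal((n, n)), 2.5)
    return blob * (1 + 0.4 * tex / tex.std())


@pytest.fixture(scope="session")
def small_phantom():
    """Default-conditions phantom at a small grid, no damaged sections."""
    spec = PhantomSpec(grid_shape=(48, 40, 48), damaged_fraction=0.0, seed=3)
    blockface, stained, truth = section_phantom(spec)
    return spec, blockface, stained, truth


@pytest.fixture(scope="session")
def jittered_phantom():
    """Phantom with default jitter/elastic/drift, used by rigid-stage tests."""
    spec = PhantomSpec(grid_shape=(64, 48, 64), damaged_fraction=0.0, seed=5)
    blockface, stained, truth = section_phantom(spec)
    return spec, blockface, stained, truth
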