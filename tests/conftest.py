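import numpy as np
import pytest

from icgquant import builtin_study
from icgquant.image import RGBImage
from icgquant.synthetic import SyntheticImageSpec, generate_synthetic_image


@pytest.fixture(scope="session")
def study():
    return builtin_study()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture()
def uniform_image():
    """64x64 noiseless field at green 147 over a dark red/blue background."""
    img, truth = generate_synthetic_image(
        SyntheticImageSpec(height=64, width=64, base_green=147, noise_sd=0.0,
                           background_rb=40, seed=1)
    )
    return img, truth


def make_image(r, g, b):
    """Build an RGBImage from per-channel scalars or arrays."""
    g = np.asarray(g)
    shape = g.shape if g.ndim else (1, 1)
    chan = lambda c: np.broadcast_to(np.asarray(c, dtype=np.uint8), shape).copy()
    return RGBImage.from_channels(chan(r), chan(g), chan(b))
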