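import numpy as np
import pytest

from nodulescan.image import GrayImage, SpacingInfo
from nodulescan.phantom import PhantomSpec, generate_slice


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def phantom_slice():
    """One default phantom slice with truth."""
    return generate_slice(PhantomSpec(seed=7))


@pytest.fixture
def quiet_phantom_slice():
    """Noise-free slice with no implanted structures."""
    spec = PhantomSpec(n_nodules=0, n_vessels=0, n_vessel_blobs=0, noise_sigma_hu=0.0, seed=7)
    return generate_slice(spec)


@pytest.fixture
def uint8_image(rng):
    px = rng.integers(0, 256, size=(64, 64)).astype(float)
    return GrayImage(px, value_domain="uint8", spacing=SpacingInfo(0.7, 0.7))


def make_bimodal_hist(rng, mu=(60, 180), sigma=(10, 10), weights=(0.5, 0.5), n_levels=256):
    """Synthetic multi-modal 8-bit histogram from Gaussian pdfs.

    Levels with negligible mixture mass are dropped: keeping them would make
    degenerate tail splits (a near-empty extreme class) score near-zero
    misclassification error, which is a pathology of the criterion rather
    than a property of the optimizer under test.
    """
    levels = np.arange(n_levels, dtype=float)
    probs = np.zeros(n_levels)
    for m, s, w in zip(mu, sigma, weights):
        probs += w * np.exp(-0.5 * ((levels - m) / s) ** 2) / s
    probs /= probs.sum()
    keep = probs > 1e-6
    return levels[keep], probs[keep] / probs[keep].sum()
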