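import numpy as np
import pytest

from glottisqc import GlottisPhantomParams, generate_pair


@pytest.fixture(scope="session")
def phantom_pairs_64():
    """Forty 64x64 phantom pairs (open glottis only), shared across tests."""
    params = GlottisPhantomParams(image_size=64, closed_probability=0.0, seed=7)
    rng = np.random.default_rng(7)
    return [generate_pair(params, rng) for _ in range(40)]


@pytest.fixture(scope="session")
def phantom_pairs_mixed_64():
    """Sixty 64x64 pairs with the default closed-glottis fraction."""
    params = GlottisPhantomParams(image_size=64, seed=11)
    rng = np.random.default_rng(11)
    return [generate_pair(params, rng) for _ in range(60)]


def random_mask(rng, shape=(16, 16), p=0.5):
    return rng.random(shape) < p


def brute_force_iou(a, b):
    """Set-based IoU oracle: explicit pixel sets, |A∩B| / |A∪B|."""
    sa = {(i, j) for i, j in zip(*np.nonzero(a))}
    sb = {(i, j) for i, j in zip(*np.nonzero(b))}
    if not sa and not sb:
        return 1.0
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)
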