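import numpy as np
import pytest

import lesionseg as ls


@pytest.fixture(scope="session")
def tiny_phantom_config():
    """Small, fast phantom world shared by training-level tests."""
    return ls.PhantomConfig(n_labeled=6, n_unlabeled=8, n_test=4,
                            image_size=(32, 32), seed=7)


@pytest.fixture(scope="session")
def tiny_split(tiny_phantom_config):
    return ls.generate_split(tiny_phantom_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def checkerboard_mask():
    yy, xx = np.mgrid[0:16, 0:16]
    return ((yy + xx) % 2).astype(np.uint8)
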