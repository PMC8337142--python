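import numpy as np
import pytest

from despeckle import default_phantom

#: Seeds of the standard evaluation phantoms used across the suite.
PHANTOM_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def phantoms():
    """The ten standard 224×224 evaluation phantoms (5 spots, 2 AW patches)."""
    return [default_phantom(seed) for seed in PHANTOM_SEEDS]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rgb(rng, h, w):
    return rng.integers(0, 256, (h, w, 3)).astype(np.uint8)
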