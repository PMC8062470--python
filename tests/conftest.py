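import numpy as np
import pytest

from dnam.fountain import make_droplets, segment_message
from dnam.codec import encode_matrix
from dnam.layout import build_default_layout

TEST_MESSAGE = b"Data is in our DNA!\n"


@pytest.fixture(scope="session")
def layout():
    return build_default_layout()


@pytest.fixture(scope="session")
def reference_store(layout):
    """The worked example: the 20-byte test message encoded into 15 origami."""
    segments = segment_message(TEST_MESSAGE, 16)
    droplets, droplet_seed = make_droplets(segments, 15, seed=42)
    matrices = [encode_matrix(d, layout) for d in droplets]
    return dict(
        message=TEST_MESSAGE,
        segments=segments,
        droplets=droplets,
        matrices=matrices,
        droplet_seed=droplet_seed,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
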