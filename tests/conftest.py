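import numpy as np
import pytest

from hifi.stack import ChannelImage, HyperplexStack


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_stack():
    """5-channel 64x64 stack with deterministic content."""
    r = np.random.default_rng(7)
    chans = [
        ChannelImage(
            r.integers(0, 60000, (64, 64)).astype(np.uint16), 0.5, f"M{i}", 0
        )
        for i in range(5)
    ]
    return HyperplexStack(chans)


@pytest.fixture(scope="session")
def nuclei_fixture():
    """A small nuclei image with ground-truth labels."""
    from hifi.synthetic import make_nuclei_image

    return make_nuclei_image(
        20, radius_range=(5, 8), density=0.01, seed=4, shape=(256, 256), pixel_size=0.5
    )
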