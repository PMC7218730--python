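import numpy as np
import pytest

from persalmap import SaliencyMap


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)


def random_map(rng, shape=(6, 6), image_id="img"):
    return SaliencyMap(image_id, rng.uniform(0.0, 1.0, size=shape), "raw")
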