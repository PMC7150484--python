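import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))  # for `reference`


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius**2).astype(np.uint8)


@pytest.fixture
def disk_mask():
    return make_disk
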