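import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # for the shared oracles module

from circmilink.io_data import InteractionDataset


@pytest.fixture
def tiny_ds() -> InteractionDataset:
    """2x2 universe with the diagonal as positives."""
    return InteractionDataset(["c1", "c2"], ["m1", "m2"], {(0, 0), (1, 1)})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
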