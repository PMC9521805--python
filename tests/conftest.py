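import numpy as np
import pytest

from ecocausal import PairedSample


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_sample(x, y):
    x = np.asarray(x, dtype=float)
    return PairedSample([f"sp{i}" for i in range(len(x))], x, np.asarray(y, dtype=float))


@pytest.fixture
def make_paired_sample():
    return make_sample
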