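import numpy as np
import pytest

from museomics import simulate


@pytest.fixture
def small_ref():
    return simulate.simulate_reference(2000, 0.45, seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(20259)
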