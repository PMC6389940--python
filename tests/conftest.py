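import numpy as np
import pytest

from hybridpaint import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return simdata.SimConfig(seed=7, sequence_length=50_000, n_strains_per_lineage=1)
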