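import numpy as np
import pytest

from rcbtl.datamodel import Hyperparams, RankingDataset
from rcbtl.simulate import generate_dataset, make_true_worths


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def hyper():
    return Hyperparams(nu=2.0, a=1.0, b=1.0)


@pytest.fixture
def small_dataset():
    """30 complete rankings of 6 objects in 2 true rank-clusters."""
    worths, _ = make_true_worths(6, 2, k1_means_singletons=False)
    return generate_dataset(30, 6, 6, worths, rng=np.random.default_rng(1))


@pytest.fixture
def empty_dataset():
    return RankingDataset(4)
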