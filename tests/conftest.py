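import numpy as np
import pytest

from vmnnet import NeuronParams, SpikeTrain
from vmnnet.fixtures import poisson_train


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def poisson_5hz_1000s():
    """Reference homogeneous Poisson train: 5 Hz, 1000 s."""
    return poisson_train(5.0, 1000.0, seed=7)


@pytest.fixture(scope="session")
def hap_only_defaults():
    """Published default neuron (HAP only: AHP and DAP amplitudes are 0)."""
    return NeuronParams()


@pytest.fixture
def small_train():
    """Tiny hand-checkable train."""
    return SpikeTrain(np.array([10.0, 30.0, 35.0, 80.0, 200.0]), 250.0)
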