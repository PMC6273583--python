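import numpy as np
import pytest

from achescreen import datasets
from achescreen.synthetic import AgentModel, NoiseModel


@pytest.fixture
def berberine():
    """Berberine-like 4PL model; slope solved from its IC10/IC90 ladder pair."""
    return AgentModel("berberine", ic50=1.48, hill=1.292)


@pytest.fixture
def coptisine():
    return AgentModel("coptisine", ic50=1.27, hill=2.936)


@pytest.fixture
def palmatine():
    return AgentModel("palmatine", ic50=5.21, hill=1.992)


@pytest.fixture
def ladders():
    return datasets.alkaloid_ladders()


@pytest.fixture
def quiet_noise():
    return NoiseModel(sd_abs=0.0, sd_rel=0.0, n_replicates=1, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20160831)
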