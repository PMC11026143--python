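import numpy as np
import pytest

from phylosym.model import Hyperparams, TopologyClassifier
from phylosym.substitution import AMINO_ACIDS, dayhoff_model


@pytest.fixture(scope="session")
def dayhoff():
    return dayhoff_model()


@pytest.fixture(scope="session")
def tiny_quartet_net():
    """Small random-parameter quartet model (equivariance is architectural)."""
    hp = Hyperparams(m=8, lstm_hidden=6, lstm_layers=2, dropout=0.2)
    return TopologyClassifier(n_taxa=4, hp=hp, seed=3)


@pytest.fixture(scope="session")
def tiny_quintet_net():
    hp = Hyperparams(m=6, lstm_hidden=5, lstm_layers=2, dropout=0.2)
    return TopologyClassifier(n_taxa=5, hp=hp, seed=4)


def random_sequences(n, length, seed):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list(AMINO_ACIDS), size=length)) for _ in range(n)]


@pytest.fixture()
def quartet_sequences():
    return random_sequences(4, 12, seed=0)


@pytest.fixture()
def quintet_sequences():
    return random_sequences(5, 10, seed=1)
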