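import numpy as np
import pytest

from rxnteacher.synthetic import CorpusSpec, generate_corpus
from rxnteacher.wln_center import WLNConfig, init_wln_params


@pytest.fixture(scope="session")
def small_corpus():
    """120 labeled + 40 unlabeled reactions, shared across unit tests."""
    return generate_corpus(CorpusSpec(n_labeled=120, n_unlabeled=40, seed=11))


@pytest.fixture(scope="session")
def tiny_params():
    """An untrained small center model for structural tests."""
    return init_wln_params(WLNConfig(depth=3, hidden_dim=16), np.random.default_rng(5))
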