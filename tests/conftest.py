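import numpy as np
import pytest

from retroseq.model import ModelConfig, init_parameters
from retroseq.synthetic import generate_dataset
from retroseq.training import build_corpus_vocabulary


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig(n_layers=1, d_model=8, n_heads=2, d_ff=16, max_len=16, dropout=0.0)


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return init_parameters(tiny_config, vocab_size=7, seed=0)


@pytest.fixture(scope="session")
def synthetic_split():
    """The default template-generated dataset (seed 0)."""
    return generate_dataset(seed=0)


@pytest.fixture(scope="session")
def synthetic_vocab(synthetic_split):
    return build_corpus_vocabulary(synthetic_split.all_records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
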