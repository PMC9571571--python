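import numpy as np
import pytest

from drugsieve.embedding import fixture_embedder
from drugsieve.synthetic import SyntheticConfig, generate_extraction_corpus


@pytest.fixture(scope="session")
def embedder():
    return fixture_embedder(seed=0)


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled corpus for unit tests (the defaults are exercised in the
    acceptance tests)."""
    return SyntheticConfig(
        n_train=48,
        n_test=24,
        n_val=24,
        tokens_per_sentence=6,
        drug_lexicon_size=8,
        distractor_vocab_size=60,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_extraction_corpus(small_config)


class StubModel:
    """Stands in for a trained regressor: predicts a fixed vector."""

    def __init__(self, vec):
        self.vec = np.asarray(vec, dtype=np.float64)

    def predict(self, X):
        return np.tile(self.vec, (len(X), 1))


@pytest.fixture
def stub_model_factory():
    return StubModel
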