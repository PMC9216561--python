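import copy

import pytest

from geomex.model import TinyTransformerAdapter, TrainConfig, fine_tune
from geomex.simulate import GeneratorConfig, generate_corpus, split_corpus, corpus_to_training_strings


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(GeneratorConfig(n_samples=150, seed=7))


@pytest.fixture(scope="session")
def small_split(small_corpus):
    return split_corpus(small_corpus, 0.8, seed=7)


@pytest.fixture(scope="session")
def trained_small_adapter(small_split):
    """Tiny backend fine-tuned on a small synthetic corpus (shared read-only;
    tests that mutate the model must deep-copy it first)."""
    train, _ = small_split
    adapter = TinyTransformerAdapter(seed=7)
    config = TrainConfig(learning_rate=1e-3, batch_size=12, max_epochs=4, seed=7)
    fine_tune(adapter, corpus_to_training_strings(train), config)
    return adapter


@pytest.fixture()
def cloned_small_adapter(trained_small_adapter):
    return copy.deepcopy(trained_small_adapter)
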