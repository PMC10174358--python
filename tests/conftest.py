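import numpy as np
import pytest
from hypothesis import settings

from discourse_n400.reservoir import ReservoirConfig, train_discourse_reservoir
from discourse_n400.semantic_space import (
    SyntheticSpaceSpec,
    generate_synthetic_space,
    generate_training_stream,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_space():
    """Tiny clustered space for fast unit tests: 4 clusters x 40 words, dim 16."""
    spec = SyntheticSpaceSpec(
        dim=16, n_clusters=4, words_per_cluster=40, within_cluster_noise=0.3, seed=101
    )
    return generate_synthetic_space(spec)


@pytest.fixture(scope="session")
def small_stream(small_space):
    return generate_training_stream(
        small_space, n_docs=80, doc_len_range=(20, 50), topic_concentration=9.0, seed=102
    )


@pytest.fixture(scope="session")
def small_reservoir(small_space, small_stream):
    """A trained small reservoir shared across order-sensitive tests."""
    config = ReservoirConfig(n_units=32, seed=103)
    return train_discourse_reservoir(small_space, small_stream, config)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
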