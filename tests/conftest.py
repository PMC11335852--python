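import numpy as np
import pytest

from groundvec import EmbeddingTable, GroundingConfig, make_world


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    return EmbeddingTable(
        words=["cat", "dog", "fish"],
        matrix=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
    )


@pytest.fixture
def small_world():
    """A compact planted world shared by training-level tests."""
    return make_world(V=60, d=8, c=4, d_img=4, seed=7, projection="identity")


@pytest.fixture
def small_config():
    return GroundingConfig(d=8, c=4, d_img=4, encoder_kind="bow",
                           encoder_units=16, batch_size=32, max_epochs=8,
                           patience=3, seed=0)
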