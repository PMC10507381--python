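import numpy as np
import pytest

from histomil import AggregatorConfig, TransformerAggregator


@pytest.fixture(scope="session")
def small_model():
    """Small untrained transformer used for math/shape checks."""
    cfg = AggregatorConfig(d_in=16, d_model=16, n_layers=2, n_heads=4,
                           mlp_hidden=32, head_hidden=16)
    return TransformerAggregator(cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
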