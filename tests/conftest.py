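import numpy as np
import pytest

from skewlearn import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_cfg(**kwargs) -> SimConfig:
    """A fast desk-scale configuration for unit tests."""
    defaults = dict(
        n_individuals=60,
        n_patches=40,
        payoff_variance=100.0,
        turnover=0.05,
        max_rounds=50,
        replicates=3,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture
def tiny_config():
    return small_cfg()
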