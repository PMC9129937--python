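import numpy as np
import pytest

from mseeg import EvalConfig, SyntheticSpec, extract_dataset_features, generate_dataset
from mseeg.classify import GoaConfig
from mseeg.selection import MacoConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """20 short recordings with a strong planted contrast (fast pipeline runs)."""
    spec = SyntheticSpec(duration=6.0, effect_size=2.0, seed=11)
    return generate_dataset(spec, 10)


@pytest.fixture(scope="session")
def small_config():
    """Reduced optimizer budgets for pipeline plumbing tests."""
    return EvalConfig(
        K=5,
        maco=MacoConfig(max_iter=10, patience=6),
        goa=GoaConfig(max_iter=15, n_grasshoppers=8),
    )


@pytest.fixture(scope="session")
def small_features(small_dataset, small_config):
    return extract_dataset_features(small_dataset, small_config)
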