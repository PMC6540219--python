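import numpy as np
import pytest

from wavelstm import GeneratorConfig, generate_feature_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_separable():
    """A small, well-separated 2-class set (dim 64) for fast classifier tests."""
    cfg = GeneratorConfig(
        n_per_class=30, n_classes=2, dim=64, sparsity=0.8,
        spike_rate_per_class=(8.0, 2.0), spike_scale=12.0, noise_sd=0.02,
        seed=42,
    )
    return cfg, generate_feature_dataset(cfg)


@pytest.fixture(scope="session")
def default_study_set():
    """The full-scale study conditions: 56 + 56 samples of 4096 features."""
    cfg = GeneratorConfig(seed=7)
    return cfg, generate_feature_dataset(cfg)
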