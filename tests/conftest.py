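import numpy as np
import pytest

from mffgnn import ModelConfig, generate_synthetic, make_splits

TOL = 1e-6  # 64-bit oracle tolerance


@pytest.fixture(scope="session")
def small_config() -> ModelConfig:
    return ModelConfig(d_h=12, d_g=10, K=2, L_mol=2, L_gcn=2, L_s=40,
                       dropout=0.0, seed=0)


@pytest.fixture(scope="session")
def tiny_dataset(small_config):
    return generate_synthetic(12, 2, 0.7, 0.1, seed=5,
                              L_s=small_config.L_s)


@pytest.fixture(scope="session")
def tiny_splits(tiny_dataset):
    return make_splits(tiny_dataset, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
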