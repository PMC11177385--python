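import numpy as np
import pytest

from neurostitch import ModelConfig, MultiTaskModel, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def tiny_config():
    """Smallest useful multi-task model: D=2, T=6, N=4, L=2."""
    return ModelConfig(D=2, T=6, N=4, L=2, head_dims=(8, 4))


@pytest.fixture
def tiny_model(tiny_config):
    return MultiTaskModel(tiny_config, rng=0)


@pytest.fixture
def tiny_spec():
    return SyntheticSpec(
        n_tasks=2,
        class_counts=((6, 6), (5, 7)),
        T=6,
        N=4,
        shared_effect=0.8,
        private_effect=0.2,
        noise_sd=1.0,
        seed=11,
    )
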