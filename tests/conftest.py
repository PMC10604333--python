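import numpy as np
import pytest

from histofed.cae import CAEConfig, build_cae
from histofed.synthetic import SynthSpec, generate_client_datasets


def micro_config(skip: bool = True) -> CAEConfig:
    """A tiny two-layer geometry (8 px) for gradient and equivalence checks."""
    return CAEConfig(
        input_size=8,
        encoder_filters=(2, 2),
        encoder_strides=(1, 2),
        bottleneck_filters=(2, 2),
        bottleneck_strides=(1, 1),
        decoder_filters=(2, 3),
        decoder_strides=(2, 1),
        latent_dim=3,
        skip_enabled=skip,
    )


@pytest.fixture(scope="session")
def micro_model():
    return build_cae(micro_config(), seed=7)


@pytest.fixture(scope="session")
def synth_datasets():
    """The default two-client study corpus (32 px patches), seeded."""
    return generate_client_datasets(SynthSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
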