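import dataclasses

import numpy as np
import pytest

from octfluidseg import ModelConfig, PhantomSpec, generate_bscan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest legal full architecture: 32x32 input, 8 base channels."""
    return ModelConfig(base_channels=8, heads=(1, 2, 4, 8), window=4,
                       input_size=32, seed=7)


@pytest.fixture
def reduced_config():
    """The scaled-down experiment configuration: 64x64 input, 16 channels.

    The channel-attention reduction shrinks with the channel count so its
    bottleneck keeps several hidden units, as it has at full scale.
    """
    return ModelConfig(base_channels=16, heads=(1, 2, 4, 8), window=4,
                       input_size=64, smffa_reduction=4, seed=7)


@pytest.fixture(scope="session")
def phantom_samples_64():
    """Eight deterministic 64x64 phantoms used across training tests."""
    spec = PhantomSpec(image_size=64, lesion_axes=(3, 10), seed=100)
    return [generate_bscan(dataclasses.replace(spec, seed=100 + i))
            for i in range(8)]
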