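import numpy as np
import pytest

from orfcall.model import ModelConfig


@pytest.fixture
def tiny_model_config():
    """A drastically shrunk architecture for fast mechanical tests."""
    return ModelConfig(
        embedding_dim=8,
        local_channels=4,
        stage_channels=(4, 6, 8),
        blocks_per_stage=(1, 1, 1),
        stage_kernels=(3, 3, 5),
        stage_dilations=(1, 2, 2),
        head_channels=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
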