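import numpy as np
import pytest

from fundusmtl.model import ModelConfig, build_model
from fundusmtl.synthetic import SynthParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model():
    """Smallest legal input size (16 px) keeps forward passes cheap."""
    return build_model(ModelConfig(input_size=16, seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Eight 32-px synthetic images with full ground truth."""
    return generate_dataset(SynthParams(n_images=8, image_size=32, seed=5))


@pytest.fixture
def float64_nn(monkeypatch):
    """Run the network in float64 for tight numerical-gradient checks."""
    import fundusmtl.nn as nn

    monkeypatch.setattr(nn, "DTYPE", np.float64)
    return nn
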