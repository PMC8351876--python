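import numpy as np
import pytest

from sscclone import ModelParams, SeedDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture
def single_as_seed():
    """Every clone starts as one singly isolated GFRα1+ cell."""
    return SeedDistribution([(1.0, {1: 1}, 0)])
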