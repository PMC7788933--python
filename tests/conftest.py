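import numpy as np
import pytest

from pyconvunet import SynthConfig, generate
from pyconvunet.networks import NetworkTopology, build_unet


@pytest.fixture(scope="session")
def organ_samples():
    """Eight 64x64 CT-like blob images, the desk-scale training fixture."""
    return generate(SynthConfig(family="organ_ct", n_images=8, size=(64, 64), seed=0))


@pytest.fixture(scope="session")
def cell_samples():
    return generate(SynthConfig(family="cell_em", n_images=4, size=(64, 64), seed=1))


@pytest.fixture()
def tiny_unet():
    """Smallest useful baseline: base width 4, one down-sampling."""
    topo = NetworkTopology(in_channels=1, out_channels=1, base_width=4,
                           n_downsamplings=1)
    return build_unet(topo, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
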