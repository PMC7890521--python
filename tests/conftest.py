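import numpy as np
import pytest

from salrsa.network import NetworkSpec, build_network
from salrsa.synthetic import generate_stimulus_set


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_spec():
    return NetworkSpec.bundled("tiny")


@pytest.fixture(scope="session")
def reference_spec():
    return NetworkSpec.bundled("reference")


@pytest.fixture(scope="session")
def micro_spec():
    """A very small net (8x8 canvas) for gradient checks and training tests."""
    return NetworkSpec.from_dict({
        "name": "micro",
        "input": {"width": 8, "height": 8, "channels": 2},
        "layers": [
            {"kind": "conv", "name": "c1", "kernel": 3, "channels": 4},
            {"kind": "relu", "name": "c1_relu"},
            {"kind": "maxpool", "name": "p1", "kernel": 2, "stride": 2},
            {"kind": "conv", "name": "c2", "kernel": 3, "channels": 3},
            {"kind": "relu", "name": "c2_relu"},
            {"kind": "deconv", "name": "d", "kernel": 4, "stride": 2,
             "channels": 1},
        ],
    })


@pytest.fixture(scope="session")
def micro_net(micro_spec):
    return build_network(micro_spec, seed=7)


@pytest.fixture(scope="session")
def small_stimuli():
    """8 categories x 8 stimuli at 32x32 - fast but category-structured."""
    return generate_stimulus_set(8, 8, seed=11, size=32)
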