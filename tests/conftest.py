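import numpy as np
import pytest

from axonquant.synth import GrowthParams, generate_neuron_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def neuron_scene():
    """One deterministic rendered neuron with its ground truth."""
    params = GrowthParams(seed=11, noise=(0.0, 0.0), min_separation_um=7.0)
    return generate_neuron_scene(params)
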