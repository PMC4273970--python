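import numpy as np
import pytest

from spikewave import ModelParameters, find_background_fixed_point, sw_cycle
from spikewave.basin import ClassificationRule


@pytest.fixture(scope="session")
def det_params():
    return ModelParameters.deterministic()


@pytest.fixture(scope="session")
def noise_params():
    return ModelParameters.noise()


@pytest.fixture(scope="session")
def det_fp(det_params):
    return find_background_fixed_point(det_params)


@pytest.fixture(scope="session")
def noise_fp(noise_params):
    return find_background_fixed_point(noise_params)


@pytest.fixture(scope="session")
def cycle(det_params):
    """One deterministic SW cycle, spike peak to spike peak."""
    return sw_cycle(det_params)


@pytest.fixture(scope="session")
def threshold_rule(det_params):
    return ClassificationRule.for_model(det_params, mode="eeg_threshold")


@pytest.fixture(scope="session")
def vicinity_rule(det_params):
    return ClassificationRule.for_model(det_params, mode="fp_vicinity")


@pytest.fixture(scope="session")
def termination_rule(det_params):
    return ClassificationRule.for_model(det_params, mode="sw_termination")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
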