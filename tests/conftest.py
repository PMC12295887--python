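import dataclasses

import numpy as np
import pytest

from pevkactin import kinetics as K


@pytest.fixture(scope="session")
def grid_2000():
    return np.arange(0.0, 2001.0, 1.0)


@pytest.fixture(scope="session")
def control_params():
    return K.KineticParams()


@pytest.fixture(scope="session")
def control_state(control_params, grid_2000):
    return K.simulate_polymerization(control_params, grid_2000)


@pytest.fixture(scope="session")
def noiseless_obs():
    return K.ObservationParams(noise_sd=0.0, k_bleach=0.0)


@pytest.fixture(scope="session")
def bleaching_obs():
    return K.ObservationParams(noise_sd=0.0, k_bleach=1e-4)


@pytest.fixture(scope="session")
def seeded_state(control_params, grid_2000):
    params = dataclasses.replace(control_params, nucleator_conc=32.5)
    return K.simulate_polymerization(params, grid_2000)
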