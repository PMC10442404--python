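import numpy as np
import pytest

from prespike import NeuronParams, PlasticityParams, filter_raster, make_two_input_pattern


@pytest.fixture(scope="session")
def nparams():
    return NeuronParams(h=0.05, tau_m=10.0, v_th=1.0)


@pytest.fixture(scope="session")
def scaled_params():
    return PlasticityParams(eta=1e-3, mode="online_scaled")


@pytest.fixture(scope="session")
def two_input_trace(nparams):
    """Filtered drive of the canonical two-spike pattern (2 ms and 6 ms)."""
    return filter_raster(make_two_input_pattern(2.0, 6.0, 500.0), nparams.h)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
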