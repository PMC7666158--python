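import numpy as np
import pytest

from phosphoswitch import ModelParameters, Protocol, ReactionNetwork
from phosphoswitch.simulate import pre_equilibrate, run_protocol


@pytest.fixture(scope="session")
def wt_params():
    return ModelParameters().with_variant("WT")


@pytest.fixture(scope="session")
def wt_network(wt_params):
    return ReactionNetwork.build(wt_params)


@pytest.fixture(scope="session")
def wt_steady_state(wt_network, wt_params):
    return pre_equilibrate(wt_network, wt_params)


@pytest.fixture(scope="session")
def anisomycin_trajectory(wt_network, wt_params, wt_steady_state):
    """Calibrated wild-type anisomycin run sampled on the blot grid."""
    return run_protocol(
        wt_network,
        wt_params,
        Protocol(sampling_times=(0.0, 300.0, 600.0, 1200.0, 2400.0)),
        initial_state=wt_steady_state.copy(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)
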