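import numpy as np
import pytest

from crnet import (IntegrationConfig, NetworkParams, STDPParams,
                   build_coupling, init_network)


@pytest.fixture(scope="session")
def params20():
    return NetworkParams(N=20)


@pytest.fixture(scope="session")
def profile20(params20):
    return build_coupling(params20)


@pytest.fixture()
def state20(params20):
    return init_network(params20, 7)


@pytest.fixture()
def cfg():
    return IntegrationConfig()


@pytest.fixture()
def stdp():
    return STDPParams()


@pytest.fixture(scope="session")
def rest_ic():
    """Non-stiff single-neuron initial condition: gating at its V=-65
    steady state (used where a smooth reference trajectory is needed)."""
    from crnet import hh_rates

    V0 = -65.0
    am, bm, ah, bh, an, bn = hh_rates(V0)
    return {
        "V": V0, "m": am / (am + bm), "h": ah / (ah + bh),
        "n": an / (an + bn), "s": 0.0,
    }
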