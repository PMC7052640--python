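import numpy as np
import pytest

from dgephys import (
    MembraneParams,
    default_granule_cell,
    make_chirp,
    simulate_subthreshold,
)


@pytest.fixture(scope="session")
def passive_cell():
    """Pure RC membrane: R = 170 MΩ, τ = 25 ms."""
    return MembraneParams(g_h=0.0, E_L=-75.0)


@pytest.fixture(scope="session")
def hcn_cell():
    """Default slow-HCN granule cell without the spike mechanism."""
    return default_granule_cell(spiking=False)


@pytest.fixture(scope="session")
def spiking_cell():
    return default_granule_cell(spiking=True)


@pytest.fixture(scope="session")
def chirp_stim():
    return make_chirp()


@pytest.fixture(scope="session")
def plain_chirp():
    """Chirp without the R̄_in prepulse (clean impedance-estimation window)."""
    return make_chirp(prepulse_duration=0.0)


@pytest.fixture(scope="session")
def hcn_chirp_trace(hcn_cell, chirp_stim):
    return simulate_subthreshold(hcn_cell, chirp_stim)


@pytest.fixture(scope="session")
def passive_chirp_trace(passive_cell, plain_chirp):
    return simulate_subthreshold(passive_cell, plain_chirp)
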