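import numpy as np
import pytest

import coalflow as cf


@pytest.fixture(scope="session")
def inflow_net():
    """Quartet MSC-I network, inflow C->B, phi=0.2, theta=0.0025."""
    return cf.quartet_network(0.0025, "msci", "inflow", phi=0.2)


@pytest.fixture(scope="session")
def small_dataset(inflow_net):
    """Three loci of 4x2 sequences, 100 sites, used across unit tests."""
    return cf.simulate_dataset(
        inflow_net, {s: 2 for s in "ABCO"}, L=3, n_sites=100, mode="msci", seed=1234
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
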