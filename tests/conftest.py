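import numpy as np
import pytest

from pitmem import DepositionParams, deposit_network


@pytest.fixture(scope="session")
def small_network():
    """A small but non-trivial deposited mat shared across tests."""
    params = DepositionParams(
        domain_x=250.0,
        domain_y=250.0,
        fibril_length=500.0,
        target_count=60,
        candidates_per_step=25,
        seed=7,
    )
    return deposit_network(params)


@pytest.fixture(scope="session")
def dense_network():
    """Denser, smaller-tile mat used by flow and mechanics tests."""
    params = DepositionParams(
        domain_x=200.0,
        domain_y=200.0,
        fibril_length=400.0,
        target_count=60,
        candidates_per_step=60,
        seed=11,
    )
    return deposit_network(params)
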