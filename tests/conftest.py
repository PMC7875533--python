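"""Shared fixtures: small, fast simulation states reused across tests."""

import numpy as np
import pytest

from bips.simulator import (
    BridgeConfig,
    ChainConfig,
    SimParams,
    init_state,
    integrate,
)


@pytest.fixture(scope="session")
def small_bridged_state():
    """A 60-bead chain with bivalent bridges, integrated briefly."""
    chain = ChainConfig(n_beads=60)
    bridges = BridgeConfig(valence=2)
    params = SimParams(seed=42, timestep=2e-4)
    state = init_state(chain, bridges, params, bridge_placement="near_chain")
    integrate(state, chain, params, 20_000, bridges=bridges, seed=7)
    return state, chain, bridges, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
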