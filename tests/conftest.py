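import numpy as np
import pytest

from nanostripe import (
    ChainParams,
    Scenario,
    SurfacePattern,
    run_scenario,
)


@pytest.fixture(scope="session")
def default_params():
    return ChainParams()


@pytest.fixture(scope="session")
def stripe_pattern():
    return SurfacePattern(geometry="stripe")


@pytest.fixture(scope="session")
def short_free_traj():
    """A short free-chain trajectory shared by analysis/io tests."""
    sc = Scenario.preset("free_uniform", seed=1234, n_steps=100_000,
                         sample_every=100)
    return run_scenario(sc)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)


def random_chain_positions(rng, params, spread=0.05):
    """A mildly perturbed random-walk configuration for force tests."""
    from nanostripe import init_chain

    state = init_chain(params, "random_walk", (0.0, 0.0), rng)
    return state.positions + rng.normal(0.0, spread, state.positions.shape)
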