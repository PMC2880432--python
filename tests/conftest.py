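import numpy as np
import pytest

from outgrowth import (
    DynamicsParams,
    SeedingSpec,
    create_grid,
    new_simulation,
)


@pytest.fixture
def small_grid():
    return create_grid(60, 60)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sim(n_agents=1, class_mix=0.0, seed=0, grid=40,
             limit_normal=None, limit_variant=None, **dyn_kwargs):
    """Small simulation helper used across dynamics/passaging tests."""
    params = DynamicsParams(division_limit_normal=limit_normal,
                            division_limit_variant=limit_variant,
                            **dyn_kwargs)
    spec = SeedingSpec(n_agents=n_agents, class_mix=class_mix, seed=seed)
    state = new_simulation(spec, params, grid_width=grid, grid_height=grid,
                           seed=seed)
    return state, params


def run_hours(state, params, hours):
    from outgrowth import step

    n = int(round(hours / params.dt))
    for _ in range(n):
        step(state, params)
    return state
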