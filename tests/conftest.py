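import numpy as np
import pytest

from dispersim.core_model import (
    PatchTypeSpec,
    ResourceSpec,
    SimulationConfig,
    validate_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_small_config(**overrides) -> SimulationConfig:
    """A fast 4-patch world with one easy and one hard resource."""
    base = dict(
        n_patches=4,
        n_individuals=10,
        n_generations=5,
        t_before=5,
        t_after=5,
        dispersal_mortality=0.1,
        learning_cost=1.4,
        mutation_prob=0.1,
        mutation_sd=0.1,
        competition_factor=2.0,
        extinction_every=None,
        extinction_count=0,
        resources=(
            ResourceSpec(1, value=1.0, handling_time=1.0, detectability=0.5),
            ResourceSpec(2, value=10.0, handling_time=20.0, detectability=0.5),
        ),
        patch_types=(
            PatchTypeSpec(1, {1: 1.0, 2: 5.0}),
            PatchTypeSpec(2, {1: 1.0, 2: 0.0}),
        ),
        patch_type_assignment=(1, 1, 2, 2),
        seed=7,
    )
    base.update(overrides)
    return validate_config(SimulationConfig(**base))


@pytest.fixture
def small_cfg() -> SimulationConfig:
    return make_small_config()
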