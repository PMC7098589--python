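import numpy as np
import pytest

from foodpolicy.synthetic import (
    SyntheticConfig,
    make_ee_vector,
    make_food_system,
    make_pe_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_bundle():
    """A seeded 5-food system with a Cournot-consistent PE matrix and a
    normalized EE vector."""
    cfg = SyntheticConfig(n_groups=5, subfoods_per_group=1, seed=42)
    gen = cfg.rng()
    system = make_food_system(cfg, gen)
    pe = make_pe_matrix(system.shares, cfg, gen)
    pe.food_id = list(system.food_id)
    ee = make_ee_vector(system.shares, cfg, gen)
    return system, pe, ee


def random_bundle(seed, n_groups=5):
    cfg = SyntheticConfig(n_groups=n_groups, subfoods_per_group=1, seed=seed)
    gen = cfg.rng()
    system = make_food_system(cfg, gen)
    pe = make_pe_matrix(system.shares, cfg, gen)
    pe.food_id = list(system.food_id)
    ee = make_ee_vector(system.shares, cfg, gen)
    return system, pe, ee
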