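import numpy as np
import pytest

from omensim.behaviour_rules import RuleParameters
from omensim.model_core import SeedingSpec
from omensim.simulation_engine import SimulationConfig


@pytest.fixture
def small_seeding():
    return SeedingSpec(n_fibroblast=40, n_mesothelial=20, n_cancer=10)


@pytest.fixture
def small_config(small_seeding):
    """12^3 lattice, 24 h: quick but long enough for every rule to fire."""
    return SimulationConfig(
        rule_params=RuleParameters(a=0.1, b=0.1, c=0.01, d=0.1, e=0.1),
        dims=(12, 12, 12),
        seeding=small_seeding,
        n_iterations=24,
        rng_seed=7,
    )


@pytest.fixture
def noop_params():
    return RuleParameters(a=0, b=0, c=0, d=0, e=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
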