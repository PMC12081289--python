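import numpy as np
import pytest

from compmap import synthetic_population as syn
from compmap.experiments import make_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_fixture():
    """Reduced population + session running the full pipeline in seconds."""
    return make_fixtures("tiny", np.random.default_rng(7))


@pytest.fixture(scope="session")
def full_population():
    """The full 600-cell conjunctive population (one build per test run)."""
    rng = np.random.default_rng(11)
    ent = syn.build_entorhinal_populations(
        syn.PopulationConfig(), (60.0, 60.0), (140.0, 120.0), rng
    )
    return ent, syn.build_conjunctive_population(ent)


@pytest.fixture(scope="session")
def full_session(full_population):
    _, pop = full_population
    return syn.simulate_replay_session(pop, np.random.default_rng(13))
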