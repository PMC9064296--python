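import numpy as np
import pytest

from gkrl import AgentParams, CohortSpec, TaskConfig, generate_cohort, make_session, simulate_agent


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A 24-game task, same structure as the full 128-game default."""
    return TaskConfig(n_games=24)


@pytest.fixture(scope="session")
def demo_params():
    return AgentParams(alpha=0.4, beta=0.12, omega=4.0, gamma=0.8)


@pytest.fixture(scope="session")
def demo_trials(small_config, demo_params):
    """One simulated subject on the small task."""
    rng = np.random.default_rng(77)
    session = make_session(small_config, rng)
    return simulate_agent(demo_params, session, small_config, rng, subject_id=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated gkRL subjects, 32 games each, with their manifest."""
    spec = CohortSpec(n_subjects=6, task=TaskConfig(n_games=32), seed=99)
    tables, manifest = generate_cohort(spec)
    return tables, manifest
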