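import numpy as np
import pytest

from twostep import AgentParams, CohortConfig, TaskConfig, simulate_session
from twostep.cohort import generate_cohort


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def session_log(task_config):
    """One deterministic default-agent session, shared across tests."""
    return simulate_session(AgentParams(), task_config, seed=20240101)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (4 + 8 participants) for pipeline-level tests."""
    config = CohortConfig(n_met_hom=4, n_val_carrier=8, n_early_first=6, seed=11)
    return generate_cohort(config)
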