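import pytest

from iblt.model import AgentParams
from iblt.task import CohortSpec, make_session_design, simulate_agent, simulate_cohort


@pytest.fixture(scope="session")
def session_trials():
    """One simulated session of a moderately deterministic agent."""
    design = make_session_design("during-task", "sham", "wins-first", seed=11)
    return simulate_agent(AgentParams(0.35, 0.2, 9.0, 5.0), design, seed=12)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject two-session cohort with no injected effects."""
    return simulate_cohort(CohortSpec(n_subjects=6, group="during-task", seed=21))
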