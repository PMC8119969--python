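import numpy as np
import pytest

from coopmpt import (
    AgentProfile,
    ExperimentDesign,
    MptParameters,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def interior_params():
    return MptParameters(C=0.4, P_Moral=0.6, P_Hypocritical=0.3, P_Antisocial=0.2, b=0.1)


@pytest.fixture(scope="session")
def two_condition_truth():
    """Distinct interior generating values for a moral/neutral experiment."""
    return {
        "moral": MptParameters(C=0.45, P_Moral=0.5, P_Hypocritical=0.3, P_Antisocial=0.2, b=0.15),
        "neutral": MptParameters(C=0.40, P_Moral=0.3, P_Hypocritical=0.25, P_Antisocial=0.2, b=0.12),
    }


@pytest.fixture(scope="session")
def exp1_design():
    """98 participants, 20 one-shot trials, asymmetric punishment."""
    return ExperimentDesign(n_participants=98)


@pytest.fixture(scope="session")
def exp1_trials(exp1_design, two_condition_truth):
    profiles = {c: AgentProfile(p) for c, p in two_condition_truth.items()}
    return simulate_experiment(exp1_design, profiles, seed=20240001)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
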