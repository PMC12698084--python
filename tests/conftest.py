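import numpy as np
import pytest

import inequitylearn as il
from inequitylearn.fit import TrialData, random_starts
from inequitylearn.models import MODELS
from inequitylearn.simulate import GenerativeAgent, REALISTIC_PRIORS


@pytest.fixture(scope="session")
def m6_agent():
    """A decisive preference-inference learner with contagion-prone weights."""
    return GenerativeAgent(
        alpha_own=3.0,
        beta_own=0.2,
        tau_own=0.2,
        model=il.get_model(6),
        learning_params=[1.0, 0.15, 0.5, 0.5],
        omega=1.0,
    )


@pytest.fixture(scope="session")
def m6_subject_records(m6_agent):
    df, _ = il.simulate_subject(m6_agent, "Adv-Dis-I-Averse", 1, seed=7, subject="s0")
    return df


@pytest.fixture(scope="session")
def m6_trial_data(m6_subject_records):
    return TrialData.from_frame(m6_subject_records)


@pytest.fixture(scope="session")
def small_cohort():
    return il.generate_cohort(3, model=6, param_priors=REALISTIC_PRIORS, master_seed=5)


def random_trial_sequences(n_seq, seed, n_trials=60, no_feedback_fraction=0.1):
    """Random (offer, action, teacher) sequences for likelihood checks."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_seq):
        type_idx = rng.integers(0, 5, size=n_trials)
        noise = rng.integers(-9, 10, size=n_trials)
        share = np.array([10, 30, 50, 70, 90])[type_idx] + noise
        action = rng.integers(0, 2, size=n_trials)
        teacher = rng.integers(0, 2, size=n_trials)
        teacher[rng.random(n_trials) < no_feedback_fraction] = -1
        out.append(
            TrialData(
                type_idx=type_idx.astype(np.int64),
                share=share.astype(float),
                action=action.astype(np.int64),
                teacher=teacher.astype(np.int64),
                weight=np.ones(n_trials),
            )
        )
    return out


def random_model_params(model, seed):
    return random_starts(MODELS[model] if isinstance(model, int) else model, 1,
                         np.random.default_rng(seed))[0]
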