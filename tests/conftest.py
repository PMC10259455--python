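import numpy as np
import pandas as pd
import pytest

from discernddm.ddm import DDMParams, simulate_trials
from discernddm.inference import GroupHyperParams
from discernddm.synth import (
    default_reaction_profile,
    generate_participants,
    generate_posts,
    simulate_reaction_study,
)


@pytest.fixture(scope="session")
def posts100():
    return generate_posts(50, 50, seed=1)


@pytest.fixture(scope="session")
def reactions_default(posts100):
    parts = generate_participants(200, seed=2)
    return simulate_reaction_study(posts100, parts, default_reaction_profile(), seed=3)


@pytest.fixture(scope="session")
def distrust_hyper():
    # exp-2 '(Dis)Trust' generating values; spreads are package defaults
    return GroupHyperParams(
        mu_v=0.216, sigma_v=0.2, mu_a=2.403, sigma_a=0.35,
        mu_z=0.48, sigma_z=0.15, mu_t0=6.681, sigma_t0=0.3,
    )


def make_trial_table(hyper, n_subj, n_trials, seed):
    """Veracity-coded trial table simulated from group-level parameters."""
    rng = np.random.default_rng(seed)
    subs = hyper.sample_subjects(n_subj, rng)
    frames = []
    for i, row in subs.iterrows():
        p = DDMParams(float(row.v), float(row.a), float(row.z), float(row.t0))
        rt, up = simulate_trials(p, n_trials, rng)
        frames.append(
            pd.DataFrame({"participant_id": f"s{i:04d}", "rt": rt, "response": up})
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_recovery_trials(distrust_hyper):
    return make_trial_table(distrust_hyper, 25, 40, seed=11)
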