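"""Shared fixtures: small simulated cohorts and estimator settings."""

import numpy as np
import pytest

from dyadte import (
    DyadCoordinationModel,
    EstimatorConfig,
    ExperimentSchedule,
    PlayerParams,
    simulate_experiment,
    simulate_trial,
)
from dyadte.preprocess import discard_initialization


@pytest.fixture(scope="session")
def config():
    return EstimatorConfig()


@pytest.fixture(scope="session")
def leader_follower_trial():
    """One full-length trial with a clear leader on the transversal axis."""
    leader = PlayerParams(coupling_in=0.5, natural_frequency=2 * np.pi + 0.15)
    follower = PlayerParams(
        coupling_in=2.0, natural_frequency=2 * np.pi - 0.15, initial_phase=1.0
    )
    trial = simulate_trial(leader, follower, seed=42, pair_id="lf")
    return discard_initialization(trial, 500)


@pytest.fixture(scope="session")
def small_cohort():
    """Five asymmetric pairs, 15 trials each, constant coupling."""
    schedule = ExperimentSchedule(n_pairs=5, trials_per_pair=15, seed=7)
    trials, truth = simulate_experiment(schedule)
    return trials, truth


@pytest.fixture(scope="session")
def fitted_cohort(small_cohort):
    trials, truth = small_cohort
    model = DyadCoordinationModel(trials)
    return model.fit(), truth


def independent_pool(n_dyads, seed, duration=25.0):
    """Uncoupled dyads (null-coupling pool) trimmed to 1,000 samples."""
    pool = []
    for s in range(n_dyads):
        p1 = PlayerParams(coupling_in=0.0)
        p2 = PlayerParams(coupling_in=0.0, initial_phase=2.0)
        trial = simulate_trial(p1, p2, seed=seed + s, duration=duration, pair_id=f"p{s}")
        pool.append(discard_initialization(trial, 500))
    return pool
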