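"""Shared fixtures: simulated datasets reused across test modules.

The expensive fixtures are session-scoped so the full-network simulations
behind the acceptance-level checks run once each.
"""

import numpy as np
import pytest

from olfsparse import pipeline
from olfsparse.network import build_connectivity
from olfsparse.params import condition_weights
from olfsparse.simulate import run_trial, trial_seed
from olfsparse.stimulus import StimulusSpec


@pytest.fixture(scope="session")
def iv_condition():
    return condition_weights("iv")


@pytest.fixture(scope="session")
def full_realization():
    return build_connectivity(seed=2020)


@pytest.fixture(scope="session")
def spontaneous_recording(full_realization, iv_condition):
    """Full model, no stimulus, 12 s of recorded activity."""
    return run_trial(full_realization, iv_condition, StimulusSpec.spontaneous(),
                     duration=12000.0, prerun=2000.0, seed=2021)


@pytest.fixture(scope="session")
def iv_stimulus_trials(full_realization, iv_condition):
    """Condition iv, odor 0, 50 standard trials."""
    return [
        run_trial(full_realization, iv_condition, StimulusSpec(0),
                  seed=trial_seed(2022, 0, 0, t))
        for t in range(50)
    ]


@pytest.fixture(scope="session")
def alpha_sweep_df():
    """Lateral-inhibition sweep, SFA on, reduced replication."""
    return pipeline.alpha_sweep(master_seed=2023, n_trials=10,
                                n_realizations=2)


@pytest.fixture(scope="session")
def decoding_tensors():
    """Feature tensors for all three sources, 20 trials per odor."""
    return pipeline.decoding_dataset(2024, n_trials=20)


@pytest.fixture(scope="session")
def sparseness_df():
    """Temporal/population sparseness for the four canonical conditions."""
    return pipeline.sparseness_grid(2025, n_trials=10)


@pytest.fixture()
def tiny_fixture():
    return pipeline.make_fixture("tiny", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
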