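"""Shared fixtures: one simulated recording session reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqtrack import decode, synth
from seqtrack._seeding import substream

settings.register_profile(
    "seqtrack",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("seqtrack")

SEED = 7


@pytest.fixture(scope="session")
def experiment() -> synth.Experiment:
    """A trained-rat session (85% complete) with a mixed 110-unit population."""
    bcfg = synth.BehaviorGenConfig(n_trials=45, p_complete=0.85, seed=SEED)
    ucfg = synth.UnitGenConfig(n_units=110, seed=SEED)
    return synth.simulate_experiment(bcfg, ucfg)


@pytest.fixture(scope="session")
def complete_trials(experiment):
    return [t for t in experiment.trials if t.valid and t.complete]


@pytest.fixture(scope="session")
def interval_tables(experiment, complete_trials) -> dict[str, np.ndarray]:
    """Per-unit 26-trial x 5-interval rate tables from the shared session."""
    tables = {
        uid: decode.build_interval_features(
            complete_trials, s, 5, 26, substream(SEED, "trial-draw", uid)
        )
        for uid, s in experiment.spikes.items()
    }
    kept, _ = decode.exclude_sparse_units(tables)
    return kept


@pytest.fixture(scope="session")
def flat_outcome_experiment() -> synth.Experiment:
    """A mid-training session (60% complete) with outcome-independent flat units."""
    bcfg = synth.BehaviorGenConfig(n_trials=120, p_complete=0.6, seed=SEED + 1)
    ucfg = synth.UnitGenConfig(n_units=30, profile_probs=(0, 0, 0, 1.0), seed=SEED + 1)
    return synth.simulate_experiment(bcfg, ucfg)
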