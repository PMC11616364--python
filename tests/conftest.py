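import numpy as np
import pytest

from antioxpred import (
    PssmProfile,
    SecondaryStructureTrack,
    SimConfig,
    simulate_dataset,
)


def make_profile(scores, sequence=None, record_id="p1"):
    scores = np.asarray(scores, dtype=float)
    if sequence is None:
        sequence = "A" * scores.shape[0]
    return PssmProfile(record_id=record_id, sequence=sequence, scores=scores)


def make_track(states, probs=None, record_id="p1"):
    if probs is None:
        probs = np.full((len(states), 3), 1.0 / 3.0)
    return SecondaryStructureTrack(record_id=record_id, states=states, probs=probs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    """A 20-record synthetic dataset on disk, reused across tests."""
    out = tmp_path_factory.mktemp("simdata")
    simulate_dataset(
        SimConfig(n_pos=10, n_neg=10, length_range=(20, 40), effect_size=3.0, seed=7),
        out,
    )
    return out
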