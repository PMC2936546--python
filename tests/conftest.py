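"""Shared fixtures: one small synthetic dataset reused across module tests."""

import numpy as np
import pytest

from hsescan import synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A modest genome with planted motifs, peaks, tag libraries and tracks."""
    genome, truth = synthetic.generate_genome(
        length=150_000,
        n_bound=30,
        n_free=30,
        n_decoy=15,
        n_kd_resistant=15,
        min_spacing=600,
        seed=7,
    )
    libs = synthetic.simulate_tag_libraries(truth, seed=8)
    tracks = synthetic.simulate_chromatin_tracks(
        truth,
        assoc_prob_bound=0.8,
        assoc_prob_free=0.1,
        signal_fold={"mark_A": 4.0, "mark_B": 4.0},
        seed=9,
    )
    return genome, truth, libs, tracks


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
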