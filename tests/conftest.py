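import numpy as np
import pytest

from shankgait import synthetic as syn


@pytest.fixture(scope="session")
def nonfrail_spec():
    return syn.cycle_spec_for_stage("non-frail")


@pytest.fixture(scope="session")
def clean_walk(nonfrail_spec):
    """Five noise-free non-frail cycles with ground truth."""
    return syn.make_walk_recording([nonfrail_spec] * 5, seed=11)


@pytest.fixture(scope="session")
def noisy_walk(nonfrail_spec):
    """Five non-frail cycles with 5 deg/s band-limited noise."""
    return syn.make_walk_recording([nonfrail_spec] * 5, noise_sd=5.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """161-subject synthetic cohort table (no recordings)."""
    return syn.make_cohort(seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
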