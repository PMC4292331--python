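import numpy as np
import pytest
from hypothesis import settings

from rangeplan.metrical import accent_strengths, build_grid, make_weights

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from rangeplan.synthetic import (GenerativeTruth, generate_cohort,
                                 generate_stimulus_pair)


@pytest.fixture(scope="session")
def stimulus_pair():
    """One seeded excerpt in its long and short contexts."""
    rng = np.random.default_rng(42)
    return generate_stimulus_pair(("C", "major"), excerpt_id=1, rng=rng)


@pytest.fixture(scope="session")
def long_score(stimulus_pair):
    return stimulus_pair[0]


@pytest.fixture(scope="session")
def short_score(stimulus_pair):
    return stimulus_pair[1]


@pytest.fixture(scope="session")
def clean_truth():
    """Generating parameters with no jitter and no corrections."""
    return GenerativeTruth(timing_jitter_sd_ms=0.0, correction_prob=0.0)


@pytest.fixture(scope="session")
def flat_profile():
    """33-position profile with a single metrical level (no accent contrast)."""
    grid = build_grid(1, 1, 33)
    return accent_strengths(grid, make_weights(1))


@pytest.fixture(scope="session")
def binary_profile():
    """33-position, 4-level binary profile with equal weights."""
    grid = build_grid(8, 4, 33)
    return accent_strengths(grid, make_weights(4, 2, 0.25))


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-participant cohort with learning trials, shared across tests."""
    return generate_cohort(n_participants=4, seed=7, include_learning=True,
                           n_learning=2)
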