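import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mgmlst import (
    MCMCConfig,
    SyntheticSchemeSpec,
    count_learning_alleles,
    curate_learning_set,
    generate_synthetic_scheme,
    learning_profile_to_ploidy,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synthetic():
    """Default 6-group, 4-locus synthetic scheme with curated learning set."""
    scheme, learning = generate_synthetic_scheme(SyntheticSchemeSpec(seed=1))
    curated, report = curate_learning_set(learning, scheme)
    assert not report
    return scheme, curated


@pytest.fixture(scope="session")
def learning_ploidy(synthetic):
    scheme, curated = synthetic
    return [learning_profile_to_ploidy(sp, scheme) for sp in curated]


@pytest.fixture(scope="session")
def learning_freqs(synthetic, learning_ploidy):
    scheme, _ = synthetic
    return count_learning_alleles(learning_ploidy, scheme)


@pytest.fixture
def fast_cfg():
    """Short chains for unit tests (not for fidelity checks)."""
    return MCMCConfig(
        burn_in=300, iterations=1500, n_runs=2, seed=11,
        classify_burn_in=50, classify_iterations=200,
    )
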