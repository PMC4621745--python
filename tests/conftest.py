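import numpy as np
import pytest

from genoinstab.io import GenomeDef
from genoinstab.synthetic import CohortConfig, simulate_cohort


@pytest.fixture
def toy_genome():
    """60 + 40 Mb two-chromosome genome used in worked FGA examples."""
    return GenomeDef((("chr1", 60_000_000), ("chr2", 40_000_000)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample cohort shared by read-only tests."""
    return simulate_cohort(CohortConfig(n_samples=60, seed=7))
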