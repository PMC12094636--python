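import numpy as np
import pytest

from msgradient import synthetic


@pytest.fixture(scope="session")
def parc():
    """62-region bilateral spherical parcellation."""
    return synthetic.generate_sphere_parcellation(30, 32, seed=1)


@pytest.fixture(scope="session")
def cohort(parc):
    """Small effect-free cohort (12 per group, 5 features)."""
    return synthetic.generate_cohort(parc, n_per_group=12, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
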