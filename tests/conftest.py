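import numpy as np
import pytest

from sofatraj.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small cohort with zero noise and zero missingness (exact round trip)."""
    cfg = CohortConfig(
        n_patients=40, noise_sd=0.0, missing_rate=0.0, full_missing_rate=0.0, seed=11
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Moderate-noise cohort without missingness, for clustering tests."""
    cfg = CohortConfig(
        n_patients=200, noise_sd=0.5, missing_rate=0.0, full_missing_rate=0.0, seed=5
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort (noise 1.0, default missingness)."""
    cfg = CohortConfig(n_patients=400, seed=3)
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
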