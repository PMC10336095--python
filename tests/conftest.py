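import numpy as np
import pytest
from hypothesis import settings

from mrwell.simdata import SimConfig, simulate_cohort

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest confounded cohort with strong per-variant effects.

    beta_g is set high enough that every variant's per-sex effect is
    sign-identifiable at this sample size, so orientation checks are
    deterministic in practice.
    """
    cfg = SimConfig(
        n_individuals=4000,
        n_variants=8,
        beta_g=0.15,
        n_regions=4,
        n_pcs=3,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = SimConfig(n_individuals=600, n_variants=4, n_regions=2, n_pcs=2, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
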