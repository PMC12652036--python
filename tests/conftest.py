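import numpy as np
import pytest

from periomics.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for structural tests (12 subjects per arm)."""
    return generate_cohort(
        CohortConfig(n_subjects_per_arm=(12, 12), seed=3, emit_site_curves=False)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (38 regimen / 45 control subjects)."""
    return generate_cohort(CohortConfig(seed=7, emit_site_curves=False))


@pytest.fixture(scope="session")
def large_cohort():
    """500 subjects per arm: the law-of-large-numbers regime."""
    return generate_cohort(
        CohortConfig(n_subjects_per_arm=(500, 500), seed=1, emit_site_curves=False)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
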