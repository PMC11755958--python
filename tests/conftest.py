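import numpy as np
import pytest

from hippostage.cohort import CohortSpec, GroupParams, generate_cohort


def make_separable_spec(n_per_group: int = 60, seed: int = 0) -> CohortSpec:
    """Cohort with disjoint per-class supports in every feature.

    Group SDs are tiny relative to the gaps, so every marker separates
    the classes perfectly; both cascade variants should reach 100%
    validation accuracy on it.  The NC-to-symptomatic volume gap is much
    wider than the MCI-to-AD gap, matching the cascade's premise that
    controls stand apart from the symptomatic pool.
    """
    groups = {
        "NC": GroupParams(4000.0, 3900.0, 5.0, 1200.0, 5.0, 200.0, 2.0, 18.0, 0.5),
        "MCI": GroupParams(2900.0, 2800.0, 5.0, 800.0, 5.0, 320.0, 2.0, 30.0, 0.5),
        "AD": GroupParams(2400.0, 2300.0, 5.0, 400.0, 5.0, 440.0, 2.0, 42.0, 0.5),
    }
    return CohortSpec(
        n_nc=n_per_group,
        n_mci=n_per_group,
        n_ad=n_per_group,
        groups=groups,
        csf_missing_rate=0.0,
        seed=seed,
    )


@pytest.fixture
def separable_cohort():
    return generate_cohort(make_separable_spec())


@pytest.fixture
def default_cohort():
    """One default-spec synthetic cohort (630 subjects, seeded)."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
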