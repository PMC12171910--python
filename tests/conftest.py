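import numpy as np
import pytest

from bodycomp import CohortSpec, HydrationTable, generate_cohort
from bodycomp.mixture import get_coefficients


@pytest.fixture(scope="session")
def ward_coeffs():
    return get_coefficients("ward")


@pytest.fixture(scope="session")
def hydration():
    return HydrationTable.default()


@pytest.fixture(scope="session")
def noiseless_spec():
    return CohortSpec(n_total=30, n_male=14, impedance_noise_sd=0.0,
                      dilution_noise_cv=0.0, ssf_noise_sd=0.0,
                      ecw_frac_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    return generate_cohort(noiseless_spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-design cohort (158 children, 75 boys)."""
    return generate_cohort(CohortSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
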