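import numpy as np
import pytest

import nnprs


@pytest.fixture(scope="session")
def small_cohort_t1d10():
    """20k-sample cohort for the 10-SNP template; shared across heavy tests."""
    prs = nnprs.make_template_prs("T1D10-like", seed=3)
    return nnprs.simulate_cohort(prs, 20_000, seed=7)


@pytest.fixture(scope="session")
def small_cohort_t1d67():
    """20k-sample cohort for the 67-SNP template with a rho=0.9 block."""
    prs = nnprs.make_template_prs("T1D67-like", seed=3)
    return nnprs.simulate_cohort(prs, 20_000, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
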