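import numpy as np
import pytest

from olre_lab import SimScenario, fit_poisson_glmm, replicate_rng, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_poisson_data():
    """3 populations x 5 observations of well-specified Poisson counts."""
    scenario = SimScenario(process="pure_poisson", n_pop=3, n_per_pop=5)
    return simulate(scenario, replicate_rng(11, 0, 0))


@pytest.fixture(scope="session")
def noise_data_mid():
    """One default-size dataset from the noise process at sigma_eps = 0.5."""
    scenario = SimScenario(process="noise", grid_value=0.5)
    return simulate(scenario, replicate_rng(42, 0, 0))


@pytest.fixture(scope="session")
def noise_fits_mid(noise_data_mid):
    """Naive and OLRE fits to the mid-noise dataset."""
    naive = fit_poisson_glmm(noise_data_mid, include_olre=False)
    olre = fit_poisson_glmm(noise_data_mid, include_olre=True)
    return naive, olre
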