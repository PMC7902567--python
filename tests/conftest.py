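import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tripletaft as ta
from tripletaft.aft import BayesianAFT

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def complete_cohort():
    """Moderate fully observed cohort for model-fitting tests."""
    cfg = ta.default_config(n=400, seed=7)
    cfg.missingness = {}
    return ta.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged registry-calibrated cohort (n=1376, with missingness)."""
    return ta.generate_cohort(ta.default_config())


@pytest.fixture(scope="session")
def big_cohort():
    """Large fully observed cohort for marginal-calibration checks."""
    cfg = ta.default_config(n=50_000, seed=99)
    cfg.missingness = {}
    return ta.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(complete_cohort):
    """A quick PFS fit with a Lauren interaction, reused across tests."""
    model = BayesianAFT(endpoint="pfs", prior_mode="weak", interactions=("lauren",),
                        n_chains=2, n_warmup=400, n_draws=800, seed=11)
    return model.fit(complete_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
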