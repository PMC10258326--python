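import numpy as np
import pytest

from psmcea.config import default_config
from psmcea.ipd import PseudoIPD, SyntheticTrialSpec, generate_synthetic_trial
from psmcea.pipeline import fit_endpoints, make_evaluator


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def trial_ipd():
    """One synthetic trial at the default (CHOICE-01-like) conditions."""
    return generate_synthetic_trial(SyntheticTrialSpec(seed=20240901))


@pytest.fixture(scope="session")
def best_fits(trial_ipd):
    """AIC-selected parametric fits for all four arm/endpoint datasets."""
    best, _tables = fit_endpoints(trial_ipd)
    return best


@pytest.fixture(scope="session")
def evaluator(cfg, best_fits):
    """Config-override -> CEResult closure with survival fits held fixed."""
    return make_evaluator(cfg, best_fits)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def lognormal_sample(rng):
    """Censored log-normal pseudo-IPD (mu=2, sigma=0.5, ~20% censored)."""
    n = 5000
    t = np.exp(2.0 + 0.5 * rng.standard_normal(n))
    c = np.exp(2.0 + 0.5 * 0.8416)  # ~80th percentile -> ~20% censoring
    return PseudoIPD(endpoint="OS", arm="TC",
                     times=np.minimum(t, c), events=(t <= c).astype(int))
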