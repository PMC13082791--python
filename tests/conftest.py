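import numpy as np
import pytest

from endoprec import synthetic_data as sd
from endoprec.specs import SubjectPopulation


@pytest.fixture(scope="session")
def small_estimation_table():
    """Two-condition estimation table, homogeneous subjects, modest size."""
    pop = SubjectPopulation(
        n_subjects=4, nu_median=1.0, nu_log_sd=0.0,
        sigma0_median=2.0, sigma0_log_sd=0.0, shared_alpha=0.5, seed=42,
    )
    priors = {k: sd.ESTIMATION_PRIORS[k] for k in ("Narrow", "Medium")}
    return pop, sd.gen_estimation(pop, priors=priors, trials_per_condition=60)


@pytest.fixture(scope="session")
def discrimination_table():
    """Two-condition discrimination table at the exponent 3/4 with lapses."""
    pn = SubjectPopulation(n_subjects=12, nu_median=0.22, nu_log_sd=0.0,
                           shared_alpha=0.75, lapse_eta=0.05, seed=7)
    pw = SubjectPopulation(n_subjects=12, nu_median=0.22, nu_log_sd=0.0,
                           shared_alpha=0.75, lapse_eta=0.05, seed=8)
    return sd.gen_discrimination(pn, pw, trials=200)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
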