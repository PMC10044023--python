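import warnings

import numpy as np
import pytest

from ceftazpk import CohortSpec, PopulationParameters, clean_dataset, sample_cohort
from ceftazpk.estimation import ModelSpec

# the final covariate structure referenced to the published eGFR value,
# used whenever estimates are compared against the generating parameters
FINAL_SPEC_REF = ModelSpec(
    continuous_cl=("EGFR_CKDEPI",), binary_cl=("ABX",), refs={"EGFR_CKDEPI": 76.86}
)


@pytest.fixture(scope="session")
def pop():
    return PopulationParameters()


@pytest.fixture(scope="session")
def default_cohort():
    """One cleaned default cohort with its truth table (fixed seed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, truth = sample_cohort(CohortSpec(), seed=42)
    return clean_dataset(ds), truth


@pytest.fixture
def rng():
    return np.random.default_rng(20230225)


def random_subject(rng, pop=None):
    """A random individual-parameter / regimen pair for oracle checks."""
    from ceftazpk import IndividualParameters, Regimen

    pop = pop or PopulationParameters()
    cl = float(np.exp(rng.normal(np.log(3.5), 0.5)))
    v = float(np.exp(rng.normal(np.log(22.0), 0.3)))
    amount = float(rng.choice([500.0, 1000.0, 2000.0]))
    interval = float(rng.choice([6.0, 8.0, 12.0, 24.0]))
    duration = float(rng.choice([0.25, 0.5, 1.0]))
    n_doses = int(np.ceil(48.0 / interval))
    reg = Regimen.uniform(amount, interval, n_doses, duration=duration)
    return IndividualParameters(cl=cl, v=v), reg
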