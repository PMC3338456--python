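import numpy as np
import pytest

from meadowsem.sem import SEMSpec, prepare_sem_data, sample_posterior
from meadowsem.synthetic import StudyDesign, TrueParams, make_design, simulate


@pytest.fixture(scope="session")
def default_design() -> StudyDesign:
    return make_design({"years": [2007, 2008]})


@pytest.fixture(scope="session")
def default_dataset(default_design):
    """24 meadows x 2 years, default generating parameters."""
    sites, meadow_years, params = simulate(default_design, TrueParams(), seed=42)
    return sites, meadow_years, params


@pytest.fixture(scope="session")
def sem_fit(default_dataset):
    """A moderate-length fit of the mid-season model, reused across tests."""
    _, meadow_years, _ = default_dataset
    data = prepare_sem_data(meadow_years, "mid")
    samples = sample_posterior(
        SEMSpec(season="mid"), data, n_chains=3, n_iter=2500, burn_in=1000, seed=7
    )
    return data, samples


@pytest.fixture
def rng():
    return np.random.default_rng(0)
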