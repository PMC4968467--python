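import numpy as np
import pytest

from dazzletrack.metrics import aggregate_cells
from dazzletrack.observer import ObserverParams, generate_dataset
from dazzletrack.session import SessionDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def paper_trials():
    """One full synthetic experiment at the canonical design (14 x 336)."""
    rng = np.random.default_rng(11)
    return generate_dataset(SessionDesign(), ObserverParams(), 14, rng)


@pytest.fixture(scope="session")
def paper_cells(paper_trials):
    analysed = paper_trials[~paper_trials["is_practice"]]
    return aggregate_cells(analysed.drop(columns=["is_practice"]))


def lmm_dataset(rng, n_groups=8, per_group=12, sigma_b=0.3, sigma_e=0.4,
                beta=(1.0, 0.5), n_covariates=1):
    """Small random-intercept dataset with known structure, for stats tests."""
    import pandas as pd

    n = n_groups * per_group
    g = np.repeat(np.arange(n_groups), per_group)
    X = np.column_stack([np.ones(n)] +
                        [rng.normal(size=n) for _ in range(n_covariates)])
    beta = np.asarray(beta[: 1 + n_covariates])
    y = X @ beta + sigma_b * rng.normal(size=n_groups)[g] + sigma_e * rng.normal(size=n)
    names = ["(Intercept)"] + [f"x{i}" for i in range(1, 1 + n_covariates)]
    data = pd.DataFrame({"participant": g, "log_error": y})
    return data, X, names
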