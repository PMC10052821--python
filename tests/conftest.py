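import numpy as np
import pandas as pd
import pytest

from favgerm.grid import GridSpec, build_hex_grid


@pytest.fixture(scope="session")
def small_grid():
    """~100-hexagon grid in a 10x10 plane (apothem in map units)."""
    return build_hex_grid(GridSpec((0.0, 0.0, 10.0, 10.0),
                                   apothem_km=0.55, km_per_degree=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230919)


def make_logistic_data(rng, n=500, beta=None, names=None, intercept=0.0):
    """Bernoulli presence from a known linear logistic surface over iid
    standard-normal covariates."""
    beta = np.asarray(beta if beta is not None else [1.0, -0.5])
    names = names or [f"x{i + 1}" for i in range(len(beta))]
    X = pd.DataFrame(rng.normal(size=(n, len(beta))), columns=names)
    eta = intercept + X.to_numpy() @ beta
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    return y.astype(float), X
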