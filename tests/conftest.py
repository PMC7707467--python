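import numpy as np
import pandas as pd
import pytest

from marweb.synthetic import mar_scenario, simulate_anomalies


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fit_data():
    """A 2-variate, 1-covariate stable MAR realization (10 years)."""
    B = np.array([[0.5, -0.2], [0.1, 0.4]])
    C = np.array([[0.3], [-0.1]])
    S = np.diag([0.4, 0.3])
    scenario = mar_scenario(B, S, C=C, a=np.array([0.05, -0.05]), n_years=10, seed=7)
    X, U = simulate_anomalies(scenario)
    return scenario, X, U


def monthly_frame(values, start="2005-01", columns=None):
    """Wrap an array as a monthly-period DataFrame."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] == 1:
        arr = arr.T
    idx = pd.period_range(start, periods=arr.shape[0], freq="M")
    idx.name = "date"
    cols = columns or [f"t{i+1}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=idx, columns=cols)
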