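import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cpmagg import IPDataset, PublishedCPM, load_tavi_cpms


@pytest.fixture(scope="session")
def tavi_cpms():
    return load_tavi_cpms()


def simulate_dataset(
    coefs: dict[str, float],
    intercept: float,
    n: int,
    rng: np.random.Generator,
    extra_covariates: list[str] | None = None,
    binary: bool = False,
) -> IPDataset:
    """Data whose outcome follows a logistic model with the given
    coefficients; extra covariates are independent noise columns."""
    names = list(coefs) + list(extra_covariates or [])
    if binary:
        X = pd.DataFrame(rng.binomial(1, 0.3, (n, len(names))).astype(float),
                         columns=names)
    else:
        X = pd.DataFrame(rng.standard_normal((n, len(names))), columns=names)
    lp = intercept + X[list(coefs)].to_numpy() @ np.array(list(coefs.values()))
    risk = expit(lp)
    return IPDataset(X, rng.binomial(1, risk), true_risk=risk)


@pytest.fixture
def small_cpm():
    return PublishedCPM("toy", -1.0, {"a": 0.8, "b": -0.5, "c": 0.4})


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
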