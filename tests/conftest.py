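import numpy as np
import pandas as pd
import pytest

import stageniche as sn


@pytest.fixture(scope="session")
def survey():
    """One default-design simulated survey shared across tests."""
    return sn.simulate_survey(seed=12345)


@pytest.fixture(scope="session")
def datasets(survey):
    return sn.assemble_datasets(survey)


@pytest.fixture(scope="session")
def published_r2():
    return sn.load_published_r2()


def make_logistic_table(rng, n, beta0=0.0, beta=(), names=()):
    """Bernoulli response under a known logit-linear model over
    independent standard-normal predictors."""
    X = rng.standard_normal((n, len(beta)))
    eta = beta0 + X @ np.asarray(beta) if len(beta) else np.full(n, beta0)
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    df = pd.DataFrame(X, columns=list(names))
    df["y"] = y
    return df
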