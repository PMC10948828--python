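import numpy as np
import pytest

import imputemean as im


@pytest.fixture(scope="session")
def table1():
    """The three benchmark (PopulationParams, DesignParams) fixtures."""
    return im.load_table1_populations()


@pytest.fixture(scope="session")
def pop1(table1):
    return table1["POP1"]


@pytest.fixture(scope="session")
def pop2(table1):
    return table1["POP2"]


@pytest.fixture(scope="session")
def pop3(table1):
    return table1["POP3"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240318)


def make_sample(rng, n=12, r=8, Xbar=None):
    """A random positive-x sample with correlated y, for identity checks."""
    x = rng.lognormal(mean=1.0, sigma=0.4, size=n)
    y = 2.0 * x + rng.normal(scale=0.5, size=n)
    y = np.abs(y) + 0.1
    if Xbar is None:
        Xbar = float(x.mean() * rng.uniform(0.8, 1.2))
    return im.SampleData(y_resp=y[:r], x_resp=x[:r], x_nonresp=x[r:], Xbar=Xbar)


@pytest.fixture()
def sample_factory(rng):
    def factory(n=12, r=8, Xbar=None):
        return make_sample(rng, n=n, r=r, Xbar=Xbar)

    return factory
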