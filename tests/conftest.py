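import numpy as np
import pytest

import funlmm as fl


@pytest.fixture(scope="session")
def small_scenario():
    """Two-family sample (n = 172) — fast but structurally realistic."""
    return fl.SimScenario(n_families=2, seed=123)


@pytest.fixture(scope="session")
def small_sample(small_scenario):
    ped, R = fl.simulate_pedigrees(small_scenario)
    eigen = fl.EigenR.from_matrix(R.R)
    return ped, R, eigen


@pytest.fixture(scope="session")
def small_null(small_sample, small_scenario):
    """A null trait and its fitted null model on the two-family sample."""
    ped, R, eigen = small_sample
    rng = np.random.default_rng(7)
    y, _ = fl.simulate_trait(ped, eigen, None, small_scenario, rng)
    X = np.ones((len(ped), 1))
    fit = fl.fit_null(y, X, eigen)
    return y, X, fit


@pytest.fixture(scope="session")
def full_sample():
    """The default eight-family (~700 individual) sample."""
    sc = fl.SimScenario(seed=11)
    ped, R = fl.simulate_pedigrees(sc)
    eigen = fl.EigenR.from_matrix(R.R)
    return sc, ped, R, eigen
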