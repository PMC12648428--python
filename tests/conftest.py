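import numpy as np
import pytest

import mapcorr as mc


@pytest.fixture(scope="session")
def fixture_dict():
    return mc.load_fixture()


@pytest.fixture(scope="session")
def spec_a(fixture_dict):
    return mc.scenario_spec("A", fixture_dict)


@pytest.fixture(scope="session")
def spec_b(fixture_dict):
    return mc.scenario_spec("B", fixture_dict)


@pytest.fixture(scope="session")
def spec_c(fixture_dict):
    return mc.scenario_spec("C", fixture_dict)


@pytest.fixture(scope="session")
def spec_d(fixture_dict):
    return mc.scenario_spec("D", fixture_dict)


@pytest.fixture(scope="session")
def spec_e(fixture_dict):
    return mc.scenario_spec("E", fixture_dict)


@pytest.fixture(scope="session")
def table_a24(spec_a):
    """One scenario-A cohort of 24 participants."""
    return mc.simulate_dataset(spec_a, 24, 20240)


def make_exact_correlation_pair(r, n, seed=0):
    """Vectors (x, y) of length n whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    u = rng.standard_normal(n)
    xc = (x - x.mean())
    xc /= np.linalg.norm(xc)
    uc = u - u.mean()
    uc -= (uc @ xc) * xc
    uc /= np.linalg.norm(uc)
    y = r * xc + np.sqrt(1 - r * r) * uc
    return x, y
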