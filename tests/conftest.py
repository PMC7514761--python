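import numpy as np
import pytest

from auxsel.models import Dataset, EMSettings, fit_em
from auxsel.simulation import generate

# Truth constants of the illustrative generative model, used throughout.
THETA0 = (0.6, -1.2, 1.2, 0.7)
PHI0 = (1.8, -1.8, 0.49, 0.0)


@pytest.fixture(scope="session")
def case1_n200():
    return generate("case1", 200, seed=42)


@pytest.fixture(scope="session")
def case1_n5000():
    return generate("case1", 5000, seed=7)


@pytest.fixture(scope="session")
def case2_n500():
    return generate("case2", 500, seed=5)


@pytest.fixture(scope="session")
def fit_b_n200(case1_n200):
    return fit_em(case1_n200, use_auxiliary=True, settings=EMSettings(seed=1))


@pytest.fixture(scope="session")
def fit_y_n200(case1_n200):
    return fit_em(case1_n200, use_auxiliary=False, settings=EMSettings(seed=1))


@pytest.fixture(scope="session")
def fit_b_n5000(case1_n5000):
    return fit_em(case1_n5000, use_auxiliary=True, settings=EMSettings(seed=2))


@pytest.fixture
def separated_data():
    """Two clusters 20 sigma apart: labels recoverable exactly."""
    rng = np.random.default_rng(3)
    n = 400
    z = (rng.random(n) < 0.5).astype(int)
    y = np.where(z == 1, -10.0, 10.0) + rng.standard_normal(n)
    a = np.where(z == 1, 5.0, -5.0) + 0.5 * rng.standard_normal(n)
    return Dataset(y=y, a=a, z=z)
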