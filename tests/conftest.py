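import numpy as np
import pytest

from mcct.io import fixture_generator
from mcct.termination import ClassificationSpec, PopulationModel


@pytest.fixture(scope="session")
def tiny_bank():
    bank, _ = fixture_generator("tiny")
    return bank


@pytest.fixture(scope="session")
def paper_bank():
    """Full-size (300 items/dimension) synthetic bank; cheap to build."""
    from mcct.study import generate_bank

    return generate_bank(np.random.default_rng(1))


@pytest.fixture(scope="session")
def tiny_examinees():
    _, examinees = fixture_generator("tiny")
    return examinees


@pytest.fixture
def spec00():
    """Cutoffs at the population mean, study defaults."""
    return ClassificationSpec(np.array([0.0, 0.0]), delta=0.2, alpha=0.05, beta=0.05)


@pytest.fixture
def pop_rho05():
    return PopulationModel.bivariate(0.5)


@pytest.fixture
def pop_rho0():
    return PopulationModel.bivariate(0.0)
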