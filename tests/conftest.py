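import numpy as np
import pytest

from uaeqc import datasets
from uaeqc.rsm import anova, fit_quadratic


@pytest.fixture(scope="session")
def factors():
    return datasets.load_factors()


@pytest.fixture(scope="session")
def published_design():
    """The 17-run design with its overall-desirability responses."""
    design, od = datasets.load_bbd_design()
    return design, od.to_numpy()


@pytest.fixture(scope="session")
def fitted_model(published_design):
    design, od = published_design
    return fit_quadratic(design, od)


@pytest.fixture(scope="session")
def published_anova(published_design, fitted_model):
    design, od = published_design
    return anova(fitted_model, design, od)


@pytest.fixture
def rng():
    return np.random.default_rng(20220710)
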