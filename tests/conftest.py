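import gc

import numpy as np
import pytest

from colliderbias import ExposureSpec, OutcomeModelParams, SelectionModelParams


@pytest.fixture(scope="session")
def exposure():
    return ExposureSpec("bernoulli", p=0.3)


@pytest.fixture(scope="session")
def logistic_outcome():
    return OutcomeModelParams("logistic", beta0=0.0, beta1=0.2)


@pytest.fixture(scope="session")
def linear_outcome():
    return OutcomeModelParams("linear", beta0=0.0, beta1=0.2, sigma=0.5)


@pytest.fixture(scope="session")
def poisson_outcome():
    return OutcomeModelParams("poisson", beta0=0.0, beta1=0.2)


@pytest.fixture(autouse=True)
def _reclaim_glm_cycles():
    """GLM result objects carry reference cycles over cohort-length arrays;
    collect them between tests to keep the suite's footprint flat."""
    yield
    gc.collect()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_selection(family="logistic", delta0=0.0, delta1=0.3, delta2=0.3, delta3=0.0, **kw):
    return SelectionModelParams(
        family=family, delta0=delta0, delta1=delta1, delta2=delta2, delta3=delta3, **kw
    )
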