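import numpy as np
import pytest

from appa_ppsr.core_model import DEFAULT_FIT_PARAMS, ModelParams, ModelState
from appa_ppsr.fitting import OxygenMap
from appa_ppsr.promoter import PromoterParams


@pytest.fixture
def default_params() -> ModelParams:
    return DEFAULT_FIT_PARAMS


@pytest.fixture
def promoter_i() -> PromoterParams:
    return PromoterParams(case="i")


@pytest.fixture
def oxygen_map() -> OxygenMap:
    return OxygenMap()


def random_state(rng, gamma: float) -> ModelState:
    """Random admissible state satisfying both conservation laws."""
    c = rng.uniform(0.0, 0.45)
    r = rng.uniform(0.0, 1.0 - 2 * c)
    p = 1.0 - r - 2 * c
    a = rng.uniform(0.0, gamma - c)
    b = gamma - a - c
    return ModelState(a=a, b=b, p=p, r=r, c=c)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170101)
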