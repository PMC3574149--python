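import numpy as np
import pytest

from cardcoal import SpeciesTree
from cardcoal.config import PriorSet
from cardcoal.core import GammaPrior


@pytest.fixture
def rng():
    return np.random.default_rng(20130215)


@pytest.fixture
def one_pop_tree():
    return SpeciesTree(["A"], [-1], [-1], [-1], [0.0], [0.01])


@pytest.fixture
def two_pop_tree():
    """Sister populations A, B diverging at tau = 0.004."""
    return SpeciesTree(["A", "B", "AB"], [2, 2, -1], [-1, -1, 0],
                       [-1, -1, 1], [0.0, 0.0, 0.004], [0.01, 0.01, 0.02])


@pytest.fixture
def priors():
    return PriorSet(theta=GammaPrior(1.0, 100.0),
                    tau_default=GammaPrior(1.0, 40.0))
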