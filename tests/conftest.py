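import numpy as np
import pytest

from lightniche import synthetic_data as sd
from lightniche.trees import Phylogeny

THETA = {"clearwing": -1.0, "confusa": 0.0, "tiger-stripe": 1.0}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def balanced4():
    """((A:1,B:1):1,(C:1,D:1):1); ultrametric depth 2."""
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def tree45():
    return sd.simulate_tree(45, seed=1)


@pytest.fixture
def painted45(tree45):
    return sd.paint_regimes(tree45, seed=2)


@pytest.fixture(scope="session")
def small_community():
    cfg = sd.SyntheticConfig(n_species=12, n_individuals=120, seed=3)
    return sd.simulate_community(cfg)
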