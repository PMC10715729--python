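import numpy as np
import pytest

from phylocomp import simulate
from phylocomp.phylo import phylo_covariance, read_newick


@pytest.fixture
def three_taxon_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree_20():
    tips = ",".join(f"t{i}:1" for i in range(20))
    return read_newick(f"({tips});")


@pytest.fixture(scope="session")
def yule50():
    return simulate.simulate_tree(50, seed=11)


@pytest.fixture(scope="session")
def yule50_cov(yule50):
    return phylo_covariance(yule50)


@pytest.fixture(scope="session")
def yule100():
    return simulate.simulate_tree(100, seed=23)


def star_tree(n: int):
    tips = ",".join(f"t{i}:1" for i in range(n))
    return read_newick(f"({tips});")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
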