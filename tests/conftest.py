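import numpy as np
import pytest

from wgdsig.speciestree import DatedSpeciesTree


@pytest.fixture(scope="session")
def two_leaf_tree():
    return DatedSpeciesTree.from_newick("(A:50,B:50);")


@pytest.fixture(scope="session")
def three_leaf_tree():
    return DatedSpeciesTree.from_newick("((A:30,B:30)i:20,C:50);")


@pytest.fixture(scope="session")
def nine_taxon_scenario():
    """Counts simulated at the default study conditions with a planted WGD."""
    from wgdsig.scenarios import build_phylo_scenario

    return build_phylo_scenario(seed=11, wgd_q=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
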