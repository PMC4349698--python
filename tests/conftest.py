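import numpy as np
import pytest

from occlusal import phylo, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def three_taxon_tree():
    return phylo.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree4():
    return phylo.read_newick("(A:2,B:2,C:2,D:2);")


@pytest.fixture
def tree13():
    return synthetic.make_tree(13, seed=7)


def random_tree(n, seed):
    return synthetic.make_tree(n, seed=seed)
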