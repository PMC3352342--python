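import numpy as np
import pytest

from flavicophy.codivtest import random_virus_trees
from flavicophy.trees import AssociationMap, PhyloTree


def random_tree(labels, rng) -> PhyloTree:
    """One uniform random rooted binary topology on ``labels``."""
    return random_virus_trees(labels, 1, rng)[0]


def random_instance(rng, n_virus, n_host):
    """A random (virus tree, host tree, many-to-one association) triple."""
    vlabels = [f"v{i}" for i in range(n_virus)]
    hlabels = [f"H{i}" for i in range(n_host)]
    virus = random_tree(vlabels, rng)
    host = random_tree(hlabels, rng)
    assoc = AssociationMap.from_pairs(
        (v, hlabels[rng.integers(n_host)]) for v in vlabels
    )
    return virus, host, assoc


@pytest.fixture
def rng():
    return np.random.default_rng(20120)
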