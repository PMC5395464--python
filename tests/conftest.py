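import numpy as np
import pytest

from fastasr import parse_newick, sim_tree, sim_traits, SimulationSpec


@pytest.fixture
def three_tip_tree():
    """The hand-checked example: C = [[2,1,0],[1,2,0],[0,0,2]]."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_tip_y():
    return np.array([1.0, 3.0, 6.0])


@pytest.fixture
def random_instance():
    """Factory for a random (tree, trait vector) pair of a given size."""

    def make(n, seed, **tree_kw):
        tree = sim_tree(n, seed=seed, **tree_kw)
        dat = sim_traits(tree, SimulationSpec(n_tips=n, seed=seed + 7919))
        return tree, dat["Y"][:, 0]

    return make
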