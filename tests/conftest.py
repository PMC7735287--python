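import numpy as np
import pytest

from phylocomp import read_tree, simulate_tree, standardize_depth
from phylocomp.simmap import RegimeMap


@pytest.fixture
def three_tip_tree():
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tip():
    return read_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def two_tip_depth1():
    return read_tree("(A:1,B:1);")


@pytest.fixture
def clade_guild_map(balanced_four_tip):
    """Two guilds that never mix: {A,B} vs {C,D}, constant through time."""
    tree = balanced_four_tip
    desc = tree.tip_descendants()
    segments = {
        v: [(0 if set(desc[v].tolist()) <= {0, 1} else 1, tree.edge_length[v])]
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    return RegimeMap(tree, ["g1", "g2"], segments)


@pytest.fixture
def bd_tree_25():
    return standardize_depth(simulate_tree(25, seed=2024), 1.0)


@pytest.fixture
def bd_tree_100():
    return standardize_depth(simulate_tree(100, seed=21), 1.0)


def single_guild_map(tree):
    """Everyone in one guild for the whole history."""
    segments = {
        v: [(0, tree.edge_length[v])]
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    return RegimeMap(tree, ["g1"], segments)
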