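import numpy as np
import pandas as pd
import pytest

import bntifeat as bf


@pytest.fixture
def four_tip_tree():
    """Two cherries: d(A,B)=d(C,D)=2, cross-cherry distances 4."""
    return bf.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def four_tip_D(four_tip_tree):
    return four_tip_tree.cophenetic()


@pytest.fixture
def cherry_table():
    """S1 holds the first cherry, S2 the second, equal abundances."""
    df = pd.DataFrame([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]],
                      index=["S1", "S2"], columns=list("ABCD"))
    return bf.CommunityTable(df, "counts")


@pytest.fixture
def singleton_table():
    """S1 = {A}, S2 = {B}: the minimal pairwise comparison."""
    df = pd.DataFrame([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]],
                      index=["S1", "S2"], columns=list("ABCD"))
    return bf.CommunityTable(df, "counts")


@pytest.fixture
def small_instance():
    """A 30-tip tree with a neutral community table, harmonized."""
    tree = bf.random_tree(30, seed=101)
    table = bf.neutral_communities(tree, n_samples=6, occupancy=0.5, seed=102)
    return table, tree.cophenetic()
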