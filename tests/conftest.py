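import numpy as np
import pytest

from paleophos import parse_dated_newick
from paleophos.simulate import SimParams, simulate_dated_tree, simulate_gene_family


@pytest.fixture
def two_leaf_tree():
    return parse_dated_newick("(A:3,B:3);")


@pytest.fixture
def three_leaf_tree():
    """Species ((A,B) at 1 Ga, C) rooted at 3 Ga."""
    return parse_dated_newick("((A:1,B:1):2,C:3);")


def surviving_family(tree, dup, trans, loss, seed):
    """First surviving simulated family at or after ``seed`` (deterministic)."""
    for s in range(seed, seed + 200):
        params = SimParams(
            dup_rate=dup, transfer_rate=trans, loss_rate=loss,
            seed=s, n_tips=len(tree.leaves()), root_age=tree.root_age,
        )
        gtree, hist = simulate_gene_family(tree, params)
        if gtree is not None and gtree.n_leaves >= 2:
            return gtree, hist
    raise RuntimeError("no surviving family found")
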