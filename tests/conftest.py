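import numpy as np
import pandas as pd
import pytest

import ecoclade as ec


@pytest.fixture
def cherry_tree():
    return ec.parse_newick("((A:1,B:1):1,C:1);")


@pytest.fixture
def three_tip_presence():
    """The worked permutation instance: rows A=(1,0), B=(1,0), C=(0,1)."""
    return pd.DataFrame(
        {"S1": [1, 1, 0], "S2": [0, 0, 1]}, index=["A", "B", "C"]
    )


def random_tree_and_table(rng, max_tips=64, max_samples=16):
    """A random Yule tree with a random integer count table on its tips."""
    n_tips = int(rng.integers(4, max_tips + 1))
    n_samples = int(rng.integers(2, max_samples + 1))
    tree = ec.simulate_tree(n_tips, rng)
    counts = rng.integers(0, 20, size=(n_tips, n_samples))
    table = pd.DataFrame(
        counts, index=tree.tip_labels,
        columns=[f"S{i}" for i in range(n_samples)],
    )
    return tree, table


@pytest.fixture
def random_tree_table_factory():
    return random_tree_and_table
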