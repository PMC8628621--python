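import numpy as np
import pandas as pd
import pytest

import phylotable as pt


@pytest.fixture
def basic_tree() -> pt.Phylogeny:
    """((A:1,B:2):3,C:4); — the canonical 3-tip example."""
    return pt.parse_newick("((A:1,B:2):3,C:4);")[0]


ANOLIS_NEWICK = "((sp1:1,sp2:1):1,((sp3:1,sp4:1):1,(sp5:1,sp6:1):1):1);"


@pytest.fixture
def anolis_like() -> pt.CoupledTreeData:
    """Six island lizards with ecomorph, body size (SVL) and a behavioral
    score, coupled to a balanced 6-tip tree."""
    tree = pt.parse_newick(ANOLIS_NEWICK)[0]
    df = pd.DataFrame(
        {
            "species": ["sp1", "sp2", "sp3", "sp4", "sp5", "sp6"],
            "island": ["Cuba", "Cuba", "Hispaniola", "Hispaniola",
                       "PuertoRico", "PuertoRico"],
            "ecomorph": ["trunk", "crown", "trunk", "crown", "trunk", "crown"],
            "SVL": [3.5, 4.0, 2.5, 5.0, 1.5, 2.0],
            "hostility": [0.5, 1.0, 0.25, 0.75, 0.5, 1.0],
        }
    )
    ctd, _ = pt.match(tree, df)
    return ctd


@pytest.fixture
def six_row_bench() -> pt.CoupledTreeData:
    """Six-taxon table shaped like the benchmark matrices (Disc*/Cont*
    columns) with hand-checkable values."""
    tree = pt.parse_newick("((s1:1,s2:1):1,((s3:1,s4:1):1,(s5:1,s6:1):1):1);")[0]
    df = pd.DataFrame(
        {
            "species": ["s1", "s2", "s3", "s4", "s5", "s6"],
            "Disc1": ["A", "A", "B", "A", "B", "A"],
            "Disc10": ["X", "Y", "X", "X", "Y", "Y"],
            "Cont2": [1.0, 2.0, 4.0, 8.0, 16.0, 32.0],
            "Cont3": [1.0, 3.0, 5.0, 7.0, 9.0, 11.0],
        }
    )
    ctd, _ = pt.match(tree, df)
    return ctd


def random_keep_set(tree: pt.Phylogeny, rng: np.random.Generator) -> set[str]:
    """Uniform random subset of tips with size >= 2."""
    tips = tree.tip_labels
    size = int(rng.integers(2, len(tips) + 1))
    return set(rng.choice(tips, size=size, replace=False))


def assert_coupled_invariant(ctd: pt.CoupledTreeData) -> None:
    """One row per tip, identical tip sets across trees, rows in the first
    tree's tip order."""
    labels = ctd.table.labels
    assert len(set(labels)) == len(labels)
    for tree in ctd.trees:
        assert tree.tip_set == set(labels)
    assert labels == ctd.trees[0].tip_labels
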