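import dendropy
import numpy as np
import pandas as pd
import pytest

from micasm.io import CommunityTable, patristic_matrix


@pytest.fixture(scope="session")
def four_leaf_tree():
    """Balanced four-leaf tree with unit branch lengths."""
    return dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                             schema="newick")


@pytest.fixture(scope="session")
def four_leaf_D(four_leaf_tree):
    return patristic_matrix(four_leaf_tree)


def abundance_vector(names, mapping):
    """Dense abundance vector aligned to ``names`` from a sparse dict."""
    v = np.zeros(len(names))
    for name, value in mapping.items():
        v[list(names).index(name)] = value
    return v


@pytest.fixture()
def toy_table():
    """3 samples x 2 OTUs with hand-checkable counts."""
    counts = pd.DataFrame([[1, 2], [3, 4], [5, 6]],
                          index=["s1", "s2", "s3"],
                          columns=["OTU_A", "OTU_B"])
    metadata = pd.DataFrame({
        "treatment": ["Control", "Control", "TCS"],
        "batch": ["B1", "B2", "B1"],
        "replicate": [1, 1, 1],
        "day": [5, 10, 5],
    }, index=counts.index)
    return CommunityTable(counts, metadata)
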