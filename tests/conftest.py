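import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from phylofunc.containers import FeatureTable, MetadataTable
from phylofunc.phylogeny import AnnotatedPhylogeny


def make_feature_table(values, samples=None, features=None, **kw) -> FeatureTable:
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(arr.shape[0])]
    features = features or [f"F{j}" for j in range(arr.shape[1])]
    return FeatureTable(pd.DataFrame(arr, index=samples, columns=features), **kw)


def make_metadata(columns: dict, types: dict, samples=None) -> MetadataTable:
    n = len(next(iter(columns.values())))
    samples = samples or [f"S{i}" for i in range(n)]
    return MetadataTable(pd.DataFrame(columns, index=samples), types)


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick")


def annotated_tree(newick: str, ko: dict[str, list[int]]) -> AnnotatedPhylogeny:
    ko_table = pd.DataFrame.from_dict(ko, orient="index").astype(int)
    ko_table.columns = [f"K{j}" for j in range(ko_table.shape[1])]
    return AnnotatedPhylogeny(tree=tree_from_newick(newick), ko_table=ko_table)


@pytest.fixture
def two_leaf_phylogeny() -> AnnotatedPhylogeny:
    """Root with leaves A (dist 1, KO vector (1,0)) and B (dist 2, (0,1))."""
    return annotated_tree("(A:1,B:2)root;", {"A": [1, 0], "B": [0, 1]})


@pytest.fixture
def cohort_meta():
    from phylofunc.synth import generate_metadata

    return generate_metadata(100, seed=11)
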