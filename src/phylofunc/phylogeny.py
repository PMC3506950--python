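"""Reference phylogeny annotated with per-genome gene (KO) content.

The tree is a rooted :class:`skbio.TreeNode` with branch lengths; each
leaf is a reference genome whose gene content is a vector of KO copy
numbers (0, 1 or multiple integer copies per KO family).  Internal nodes
receive reconstructed copy-number vectors (see
:mod:`phylofunc.inference`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import ValidationError


def name_internal_nodes(tree: TreeNode) -> TreeNode:
    """Give every unnamed internal node a deterministic preorder name."""
    existing = {n.name for n in tree.traverse() if n.name is not None}
    counter = 0
    for node in tree.preorder():
        if node.name is None:
            counter += 1
            name = f"node{counter:04d}"
            while name in existing:
                counter += 1
                name = f"node{counter:04d}"
            node.name = name
            existing.add(name)
    return tree


@dataclass
class AnnotatedPhylogeny:
    """Rooted tree plus a genomes x KOs copy-number table.

    Attributes
    ----------
    tree
        Rooted skbio tree; every node carries a unique name.
    ko_table
        Genomes x KO families, integer copy numbers; indexed by leaf name.
    unannotated
        Leaf names present in the tree but absent from ``ko_table``.
    node_vectors
        Nodes x KOs table filled by ancestral reconstruction; leaves hold
        their own genome vectors.  ``None`` before reconstruction.
    unreconstructed
        Internal nodes with no annotated descendant leaf (no vector).
    """

    tree: TreeNode
    ko_table: pd.DataFrame
    unannotated: list[str] = field(default_factory=list)
    node_vectors: pd.DataFrame | None = None
    unreconstructed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} above node {node.name!r}"
                )
        name_internal_nodes(self.tree)
        names = [n.name for n in self.tree.traverse()]
        if len(names) != len(set(names)):
            raise ValidationError("tree node names are not unique")

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def node(self, name: str) -> TreeNode:
        return self.tree.find(name)

    def leaf_distances(self) -> dict[str, list[tuple[str, float]]]:
        """Per node, the (leaf name, path length down to leaf) pairs.

        The distance from a node to one of its descendant leaves is the
        sum of branch lengths on the connecting path; a node is at
        distance 0 from itself.
        """
        out: dict[str, list[tuple[str, float]]] = {}
        for node in self.tree.postorder():
            if node.is_tip():
                out[node.name] = [(node.name, 0.0)]
            else:
                pairs: list[tuple[str, float]] = []
                for child in node.children:
                    pairs.extend(
                        (leaf, d + child.length) for leaf, d in out[child.name]
                    )
                out[node.name] = pairs
        return out

    def descendant_leaf_sets(self) -> dict[str, frozenset[str]]:
        """Per node, the set of descendant leaf names (a leaf maps to itself)."""
        out: dict[str, frozenset[str]] = {}
        for node in self.tree.postorder():
            if node.is_tip():
                out[node.name] = frozenset([node.name])
            else:
                out[node.name] = frozenset().union(
                    *(out[c.name] for c in node.children)
                )
        return out


def read_annotated_tree(
    tree_path: str | Path,
    genome_ko_path: str | Path,
    *,
    allow_unannotated: bool = False,
) -> AnnotatedPhylogeny:
    """Read a Newick tree and its genome x KO copy-number table.

    Every leaf must appear in the genome table unless
    ``allow_unannotated`` is set, in which case missing leaves are
    flagged and excluded from reconstruction.
    """
    tree = TreeNode.read(str(tree_path), format="newick")
    ko_table = read_genome_ko(genome_ko_path)
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in ko_table.index]
    if missing and not allow_unannotated:
        raise ValidationError(
            f"tree leaves absent from genome KO table: {missing}"
        )
    return AnnotatedPhylogeny(tree=tree, ko_table=ko_table, unannotated=missing)


def read_genome_ko(path: str | Path) -> pd.DataFrame:
    """Read a genomes x KOs TSV of integer copy numbers."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(f"{path}: genome KO table has missing cells")
    if (values < 0).any():
        raise ValidationError(f"{path}: negative KO copy numbers")
    if not np.allclose(values, np.round(values)):
        raise ValidationError(f"{path}: KO copy numbers must be integers")
    df = df.astype(int)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_genome_ko(ko_table: pd.DataFrame, path: str | Path) -> None:
    ko_table.to_csv(path, sep="\t", index_label="genome")


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
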