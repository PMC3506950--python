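"""Metagenome inference from community composition.

Given a 16S-derived taxon abundance table, a reference phylogeny whose
leaves are genomes annotated with KO (KEGG ortholog) copy-number
vectors, and a taxonomy linking phylotype names to reference genomes,
the method estimates each sample's gene-family content in three steps:

1. **Clade mapping** — every taxonomy clade (genus upward) is assigned
   the tree node maximizing the Jaccard index between the clade's
   genome set and the node's descendant-genome set.
2. **Ancestral gene-content reconstruction** — each internal node *g*
   receives the weighted average of its descendant leaf vectors *h*,

       g = sum_h w(g, h) h / sum_h w(g, h),   w(g, h) = 2^(-dist(g, h)),

   with dist the branch-length path from *g* down to *h*, so nearby
   genomes dominate the reconstruction.
3. **Composition** — per sample, each KO's abundance is the sum over
   phylotypes of (phylotype abundance x that phylotype's node copy
   number), optionally renormalized to per-sample relative abundance.

A naive gene-set rollup (mean or sum over member KOs) is provided for
pathway-level summaries; it is deliberately simple and does no
parsimony-based pathway calling or gap filling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FeatureTable, ValidationError
from .phylogeny import AnnotatedPhylogeny

logger = logging.getLogger(__name__)


@dataclass
class CladeMapping:
    """Taxonomy clade -> (tree node, Jaccard score, tie count)."""

    assignments: dict[str, tuple[str, float, int]] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)

    def node_of(self, clade: str) -> str:
        return self.assignments[clade][0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": c, "node": n, "jaccard": j, "tie_count": t}
            for c, (n, j, t) in self.assignments.items()
        ]
        rows += [
            {"clade": c, "node": "", "jaccard": np.nan, "tie_count": 0}
            for c in self.unmapped
        ]
        return pd.DataFrame(rows, columns=["clade", "node", "jaccard", "tie_count"])


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def map_taxonomy_to_tree(
    taxonomy: Mapping[str, set[str] | frozenset[str]],
    phylogeny: AnnotatedPhylogeny,
) -> CladeMapping:
    """Assign each taxonomy clade the tree node with maximal Jaccard
    overlap of descendant genome names.

    Ties go to the node with fewer descendant genomes (the most specific
    clade), then to the lexicographically smallest node name; the number
    of co-optimal nodes is recorded.  Clades with no overlap anywhere,
    or with an empty genome annotation, are reported unmapped.
    """
    leaf_sets = phylogeny.descendant_leaf_sets()
    nodes = sorted(leaf_sets)  # deterministic scan order
    mapping = CladeMapping()
    for clade, genomes in taxonomy.items():
        genomes = frozenset(genomes)
        if not genomes:
            logger.warning("clade %r has no genome annotation; unmapped", clade)
            mapping.unmapped.append(clade)
            continue
        scored = [
            (jaccard(genomes, leaf_sets[name]), name) for name in nodes
        ]
        best_j = max((j for j, _ in scored), default=0.0)
        if best_j <= 0:
            mapping.unmapped.append(clade)
            continue
        candidates = [name for j, name in scored if j == best_j]
        # ties: prefer the most specific clade, then lexicographic name
        winner = min(candidates, key=lambda n: (len(leaf_sets[n]), n))
        mapping.assignments[clade] = (winner, best_j, len(candidates))
    return mapping


def reconstruction_weight(distance: float) -> float:
    """w = 2^(-distance): halves per unit of branch length."""
    if distance < 0:
        raise ValueError(f"negative phylogenetic distance {distance!r}")
    return float(2.0 ** (-distance))


def reconstruct_gene_content(phylogeny: AnnotatedPhylogeny) -> AnnotatedPhylogeny:
    """Fill every node's KO vector from its annotated descendant leaves.

    Internal vectors are the 2^(-dist)-weighted average over descendant
    leaf genomes; leaves keep their own integer vectors.  Nodes with no
    annotated descendant are flagged in ``unreconstructed``.
    """
    ko_table = phylogeny.ko_table
    annotated = set(ko_table.index) - set(phylogeny.unannotated)
    dists = phylogeny.leaf_distances()
    vectors: dict[str, np.ndarray] = {}
    unreconstructed: list[str] = []
    ko_values = ko_table.to_numpy(dtype=float)
    row_of = {g: i for i, g in enumerate(ko_table.index)}
    for name, pairs in dists.items():
        usable = [(leaf, d) for leaf, d in pairs if leaf in annotated]
        if not usable:
            unreconstructed.append(name)
            continue
        weights = np.array([reconstruction_weight(d) for _, d in usable])
        rows = ko_values[[row_of[leaf] for leaf, _ in usable]]
        vectors[name] = weights @ rows / weights.sum()
    node_vectors = pd.DataFrame.from_dict(vectors, orient="index", dtype=float)
    node_vectors.columns = ko_table.columns
    phylogeny.node_vectors = node_vectors
    phylogeny.unreconstructed = unreconstructed
    return phylogeny


def infer_ko_abundance(
    taxa_table: FeatureTable,
    mapping: CladeMapping,
    phylogeny: AnnotatedPhylogeny,
    *,
    renormalize: bool = True,
) -> tuple[FeatureTable, pd.Series]:
    """Compose per-sample KO abundances from mapped phylotypes.

    KO_i(sample) = sum over mapped phylotypes g of
    abundance(sample, g) x reconstructed copy number g[i].  Phylotypes
    with no mapping contribute nothing; their total abundance per sample
    is returned as the skipped-mass series.  With ``renormalize`` (the
    default) each sample is rescaled to relative abundance; a sample
    with no mapped phylotype mass raises.
    """
    if phylogeny.node_vectors is None:
        phylogeny = reconstruct_gene_content(phylogeny)
    mapped = [f for f in taxa_table.feature_ids if f in mapping.assignments]
    skipped = [f for f in taxa_table.feature_ids if f not in mapping.assignments]
    if not mapped:
        raise ValidationError("no phylotype in the table is mapped to the tree")
    node_vectors = phylogeny.node_vectors
    gene_matrix = node_vectors.loc[
        [mapping.node_of(f) for f in mapped]
    ].to_numpy(dtype=float)
    abund = taxa_table.data[mapped].to_numpy(dtype=float)
    ko = abund @ gene_matrix
    skipped_mass = pd.Series(
        taxa_table.data[skipped].sum(axis=1) if skipped else 0.0,
        index=taxa_table.data.index,
        name="skipped_mass",
        dtype=float,
    )
    result = pd.DataFrame(ko, index=taxa_table.data.index, columns=node_vectors.columns)
    if renormalize:
        sums = result.sum(axis=1)
        zero = sums.index[sums <= 0]
        if len(zero):
            raise ValidationError(
                f"sample {zero[0]!r} has no mapped phylotype abundance; "
                "cannot renormalize"
            )
        result = result.div(sums, axis=0)
    table = FeatureTable(result, feature_kind="gene", relative=renormalize)
    return table, skipped_mass


def rollup_gene_sets(
    ko_table: FeatureTable,
    gene_set_map: Mapping[str, list[str]],
    how: str = "mean",
) -> FeatureTable:
    """Aggregate KO abundances into gene-set abundances (mean or sum).

    Gene sets with no member KO present in the table are dropped with a
    warning.  This is a naive rollup: no pathway parsimony, smoothing or
    gap filling.
    """
    if how not in ("mean", "sum"):
        raise ValueError("how must be 'mean' or 'sum'")
    columns = {}
    for gs, members in gene_set_map.items():
        present = [m for m in members if m in ko_table.data.columns]
        if not present:
            logger.warning("gene set %r has no member KO in the table; dropped", gs)
            continue
        block = ko_table.data[present]
        columns[gs] = block.mean(axis=1) if how == "mean" else block.sum(axis=1)
    if not columns:
        raise ValidationError("no gene set has any member KO present")
    df = pd.DataFrame(columns)
    return FeatureTable(df, feature_kind="gene_set", relative=False)


def per_sample_spearman(inferred: FeatureTable, truth: FeatureTable) -> pd.Series:
    """Spearman rank correlation of inferred vs true KO profile, per sample.

    This is the validation protocol for the inference step: each
    sample's inferred gene-family abundances are rank-correlated with
    the profile obtained from the true genomes.  Rank correlation is
    insensitive to per-sample renormalization.
    """
    from scipy.stats import spearmanr

    common = [c for c in inferred.data.columns if c in truth.data.columns]
    if len(common) < 2:
        raise ValidationError("need >= 2 shared KO features to correlate")
    out = {}
    for sid in inferred.data.index:
        rho = spearmanr(
            inferred.data.loc[sid, common], truth.data.loc[sid, common]
        ).statistic
        out[sid] = float(rho)
    return pd.Series(out, name="spearman_rho")


class GeneContentInferrer(BaseEstimator, TransformerMixin):
    """Taxon table -> inferred KO table, as a fitted transformer.

    ``fit`` takes the reference phylogeny and taxonomy: it reconstructs
    ancestral gene content and maps taxonomy clades onto tree nodes.
    ``transform`` then converts any taxon abundance table whose features
    are taxonomy clades into a per-sample KO abundance table.

    Attributes
    ----------
    mapping_ : CladeMapping
    phylogeny_ : AnnotatedPhylogeny  (with ``node_vectors`` filled)
    skipped_mass_ : pd.Series        (per sample, from the last transform)
    """

    def __init__(self, renormalize: bool = True):
        self.renormalize = renormalize

    def fit(
        self,
        phylogeny: AnnotatedPhylogeny,
        taxonomy: Mapping[str, set[str]] | None = None,
    ) -> "GeneContentInferrer":
        self.phylogeny_ = reconstruct_gene_content(phylogeny)
        if taxonomy is None:  # identity taxonomy: phylotypes are leaves
            taxonomy = {l: {l} for l in phylogeny.leaf_names}
        self.mapping_ = map_taxonomy_to_tree(taxonomy, self.phylogeny_)
        return self

    def transform(self, taxa_table: FeatureTable) -> FeatureTable:
        table, self.skipped_mass_ = infer_ko_abundance(
            taxa_table, self.mapping_, self.phylogeny_,
            renormalize=self.renormalize,
        )
        return table
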