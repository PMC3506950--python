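"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis
assumes:

- :func:`generate_metadata` draws a mixed-type clinical metadata table
  (disease status, sample origin, age, smoking, treatments whose
  probabilities depend on disease) with injected missingness;
- :func:`generate_communities` runs the association model generatively:
  per feature, a baseline mean on the arcsine-square-root scale plus
  planted linear metadata effects plus Gaussian noise, back-transformed
  through sin^2 and renormalized to a compositional table;
- :func:`generate_annotated_tree` simulates a coalescent reference
  phylogeny whose leaf genomes evolved KO copy numbers by per-branch
  gain/loss (so gene content correlates with phylogeny), together with
  a rank taxonomy consistent with tree clades.

:func:`generate_paired_metagenome` produces the matching "measured"
metagenome — the abundance-weighted mixture of true leaf genomes —
against which inferred profiles are scored by Spearman correlation.

Every generator is a pure function of its spec and seed.  Each
generator salts the user seed with a distinct constant, so feeding one
seed to several generators yields statistically independent draws.
"""

from __future__ import annotations

import io as _io
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .containers import FeatureTable, MetadataTable, ValidationError
from .inference import CladeMapping
from .phylogeny import AnnotatedPhylogeny
from .qc import arcsine_sqrt

HALF_PI = float(np.pi / 2)

# per-generator seed salts: one user seed, independent streams
_SALT_METADATA = 101
_SALT_COMMUNITIES = 202
_SALT_DIRICHLET = 303
_SALT_TREE = 404
_SALT_LEAF_COMMUNITIES = 505


# ---------------------------------------------------------------- metadata

@dataclass
class MetadatumSpec:
    """Recipe for one synthetic metadata column.

    Categorical columns draw levels with ``probs`` (or, when
    ``conditional_on`` names another categorical column,
    ``conditional_probs[level_of_parent]``); continuous columns are
    Gaussian with ``mean``/``sd``.  ``missing_rate`` cells are blanked
    after drawing.
    """

    name: str
    kind: str = "categorical"
    levels: Sequence[str] | None = None
    probs: Sequence[float] | None = None
    conditional_on: str | None = None
    conditional_probs: dict[str, Sequence[float]] | None = None
    mean: float = 0.0
    sd: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"{self.name}: kind must be categorical/continuous")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"{self.name}: categorical spec needs levels")
            for probs in (
                [self.probs] if self.probs is not None
                else list((self.conditional_probs or {}).values())
            ):
                if probs is None or abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(f"{self.name}: level probabilities must sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"{self.name}: missing_rate must be in [0, 1)")


def cohort_metadata_specs() -> list[MetadatumSpec]:
    """Default cohort recipe: an IBD-style case/control study.

    Disease status (healthy/CD/UC, weighted toward cases as in referral
    cohorts), stool-vs-biopsy sample origin, age, smoking history with
    some missingness, and four treatments whose frequency depends on
    disease status (immunosuppressants and steroids concentrated in CD,
    mesalamine in UC).
    """
    return [
        MetadatumSpec("disease", levels=["healthy", "CD", "UC"],
                      probs=[0.12, 0.54, 0.34]),
        MetadatumSpec("sample_origin", levels=["stool", "biopsy"],
                      probs=[0.55, 0.45]),
        MetadatumSpec("age", kind="continuous", mean=38.0, sd=15.0,
                      missing_rate=0.05),
        MetadatumSpec("smoking", levels=["never", "former", "current"],
                      probs=[0.55, 0.25, 0.20], missing_rate=0.05),
        MetadatumSpec("antibiotics", levels=["no", "yes"], conditional_on="disease",
                      conditional_probs={"healthy": [0.95, 0.05],
                                         "CD": [0.75, 0.25],
                                         "UC": [0.80, 0.20]}),
        MetadatumSpec("immunosuppressant", levels=["no", "yes"],
                      conditional_on="disease",
                      conditional_probs={"healthy": [0.98, 0.02],
                                         "CD": [0.50, 0.50],
                                         "UC": [0.70, 0.30]}),
        MetadatumSpec("mesalamine", levels=["no", "yes"], conditional_on="disease",
                      conditional_probs={"healthy": [0.98, 0.02],
                                         "CD": [0.70, 0.30],
                                         "UC": [0.35, 0.65]}),
        MetadatumSpec("steroids", levels=["no", "yes"], conditional_on="disease",
                      conditional_probs={"healthy": [0.98, 0.02],
                                         "CD": [0.65, 0.35],
                                         "UC": [0.75, 0.25]}),
    ]


def generate_metadata(
    n_samples: int,
    specs: Sequence[MetadatumSpec] | None = None,
    seed: int = 0,
) -> MetadataTable:
    """Draw a metadata table from the given specs (cohort recipe by default)."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    specs = list(specs) if specs is not None else cohort_metadata_specs()
    rng = np.random.default_rng([seed, _SALT_METADATA])
    index = [f"S{i:04d}" for i in range(n_samples)]
    data: dict[str, np.ndarray | list] = {}
    types: dict[str, str] = {}
    for spec in specs:
        if spec.kind == "continuous":
            col: np.ndarray | list = rng.normal(spec.mean, spec.sd, n_samples)
        elif spec.conditional_on is not None:
            parent = data[spec.conditional_on]
            col = [
                str(rng.choice(spec.levels, p=spec.conditional_probs[str(pv)]))
                for pv in parent
            ]
        else:
            col = [str(v) for v in rng.choice(spec.levels, p=spec.probs, size=n_samples)]
        data[spec.name] = col
        types[spec.name] = spec.kind
    df = pd.DataFrame(data, index=index)
    for spec in specs:  # inject missingness after all draws
        if spec.missing_rate > 0:
            mask = rng.random(n_samples) < spec.missing_rate
            df.loc[mask, spec.name] = np.nan
    return MetadataTable(df, types)


# ------------------------------------------------------------- communities

@dataclass
class PlantedEffect:
    """A linear effect on the arcsine-sqrt scale: response shifts by
    ``beta`` per unit of the encoded covariate (level indicator for a
    categorical level, z-score for a continuous metadatum)."""

    feature: str
    metadatum: str
    beta: float
    level: str | None = None


@dataclass
class SyntheticTruth:
    """Everything needed to verify recovery of the planted structure."""

    effects: list[PlantedEffect]
    noise_sd: float
    seed: int
    baselines: pd.Series
    pre_norm: pd.DataFrame  # back-transformed abundances before renormalization
    arcsine_values: pd.DataFrame | None = None  # latent z before clamping
    clamped_fraction: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": e.feature, "metadatum": e.metadatum,
             "level": e.level or "", "beta": e.beta}
            for e in self.effects
        ]
        return pd.DataFrame(rows, columns=["feature", "metadatum", "level", "beta"])


def _effect_covariate(meta: MetadataTable, effect: PlantedEffect) -> np.ndarray:
    col = meta.data[effect.metadatum]
    if meta.types[effect.metadatum] == "categorical":
        if effect.level is None:
            raise ValueError(f"effect on {effect.metadatum!r} needs a level")
        return (col.astype(str) == effect.level).to_numpy(dtype=float)
    x = col.to_numpy(dtype=float)
    filled = np.where(np.isnan(x), np.nanmean(x), x)
    sd = filled.std()
    return (filled - filled.mean()) / (sd if sd > 0 else 1.0)


def generate_communities(
    meta: MetadataTable,
    n_features: int = 50,
    effects: Sequence[PlantedEffect] = (),
    seed: int = 0,
    noise_sd: float = 0.1,
    feature_prefix: str = "T",
    feature_ids: Sequence[str] | None = None,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Generate a compositional feature table with planted linear effects.

    Per feature j and sample i:
    z_ij = mu_j + sum of planted beta x covariate + N(0, noise_sd),
    clamped to [0, pi/2]; abundance = sin^2(z); samples renormalized to
    sum to 1.  The truth records the pre-normalization table (planted
    group differences are exact on the arcsine scale only before
    renormalization).  ``feature_ids`` overrides the generated names
    (e.g. to use reference-tree leaf names as phylotypes).
    """
    effects = list(effects)
    rng = np.random.default_rng([seed, _SALT_COMMUNITIES])
    if feature_ids is not None:
        features = list(feature_ids)
        if len(features) != n_features:
            raise ValueError("feature_ids length must equal n_features")
    else:
        features = [f"{feature_prefix}{j:04d}" for j in range(n_features)]
    known = set(features)
    for e in effects:
        if e.feature not in known:
            raise ValueError(f"planted effect on unknown feature {e.feature!r}")
        if e.metadatum not in meta.names:
            raise ValueError(f"planted effect on unknown metadatum {e.metadatum!r}")
    n = len(meta.data)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=n_features)
    base_props = raw / raw.sum()
    mu = arcsine_sqrt(base_props)
    z = np.tile(mu, (n, 1))
    for e in effects:
        j = features.index(e.feature)
        z[:, j] += e.beta * _effect_covariate(meta, e)
    z += rng.normal(0.0, noise_sd, size=z.shape)
    z_latent = pd.DataFrame(z.copy(), index=meta.data.index, columns=features)
    clamped = float(np.mean((z < 0) | (z > HALF_PI)))
    if clamped > 0.05:
        import warnings

        warnings.warn(f"{clamped:.1%} of arcsine-scale values clamped to [0, pi/2]")
    z = np.clip(z, 0.0, HALF_PI)
    pre = np.sin(z) ** 2
    pre_df = pd.DataFrame(pre, index=meta.data.index, columns=features)
    post = pre_df.div(pre_df.sum(axis=1), axis=0)
    truth = SyntheticTruth(
        effects=effects,
        noise_sd=noise_sd,
        seed=seed,
        baselines=pd.Series(mu, index=features, name="baseline_arcsine"),
        pre_norm=pre_df,
        arcsine_values=z_latent,
        clamped_fraction=clamped,
    )
    return FeatureTable(post, feature_kind="taxon", relative=True), truth


def generate_communities_dirichlet(
    meta: MetadataTable,
    n_features: int = 50,
    effects: Sequence[PlantedEffect] = (),
    seed: int = 0,
    concentration: float = 1.0,
    feature_prefix: str = "T",
) -> tuple[FeatureTable, SyntheticTruth]:
    """Model-mismatch alternative: gamma-compositional abundances with
    multiplicative (log-scale) planted effects, for robustness checks of
    the association stage under a generative model it does not assume."""
    effects = list(effects)
    rng = np.random.default_rng([seed, _SALT_DIRICHLET])
    features = [f"{feature_prefix}{j:04d}" for j in range(n_features)]
    n = len(meta.data)
    base = rng.lognormal(0.0, 1.0, n_features)
    log_alpha = np.tile(np.log(base), (n, 1))
    for e in effects:
        j = features.index(e.feature)
        log_alpha[:, j] += e.beta * _effect_covariate(meta, e)
    draws = rng.gamma(shape=concentration, scale=np.exp(log_alpha))
    pre_df = pd.DataFrame(draws, index=meta.data.index, columns=features)
    post = pre_df.div(pre_df.sum(axis=1), axis=0)
    truth = SyntheticTruth(
        effects=effects, noise_sd=float("nan"), seed=seed,
        baselines=pd.Series(np.log(base), index=features, name="log_baseline"),
        pre_norm=pre_df,
    )
    return FeatureTable(post, feature_kind="taxon", relative=True), truth


# -------------------------------------------------------- tree & metagenome

@dataclass
class SyntheticReference:
    """A simulated reference set: annotated phylogeny + consistent taxonomy."""

    phylogeny: AnnotatedPhylogeny
    taxonomy: dict[str, frozenset[str]]  # clade name -> genome names
    genera: dict[str, frozenset[str]]    # genus-rank subset of taxonomy
    newick: str


def _partition_genera(tree: TreeNode, max_size: int) -> list[frozenset[str]]:
    """Cut the tree into disjoint clades of at most ``max_size`` leaves."""
    groups: list[frozenset[str]] = []
    stack = [tree]
    while stack:
        node = stack.pop()
        tips = frozenset(t.name for t in ([node] if node.is_tip() else node.tips()))
        if len(tips) <= max_size or node.is_tip():
            groups.append(tips)
        else:
            stack.extend(reversed(node.children))
    return groups


def generate_annotated_tree(
    n_leaves: int = 32,
    n_kos: int = 40,
    seed: int = 0,
    *,
    branch_scale: float = 0.5,
    gain_loss_rate: float = 0.5,
    genus_size: int = 4,
    mismatch: float = 0.0,
) -> SyntheticReference:
    """Simulate the reference set: coalescent tree, evolved KO content,
    and a tree-consistent rank taxonomy.

    Branch lengths are Kingman coalescent times scaled by
    ``branch_scale``; KO copy numbers start from a root vector drawn
    over {0, 1, 2} and take +/-1 steps per branch with probability
    ``1 - exp(-gain_loss_rate * branch_length)`` per KO, clipped at 0,
    so related genomes share gene content.  The taxonomy holds
    genus-rank clades (tree cuts of at most ``genus_size`` leaves) plus
    one higher rank per root subtree; ``mismatch`` reassigns that
    fraction of genomes to a random other genus, breaking perfect
    tree-taxonomy agreement.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    labels = [f"G{i:04d}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    dtree = treesim.pure_kingman_tree(
        taxon_namespace=tns,
        pop_size=1.0,
        rng=random.Random(int(np.random.SeedSequence([seed, _SALT_TREE]).generate_state(1)[0])),
    )
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length) * branch_scale
    newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    tree = TreeNode.read(_io.StringIO(newick), format="newick")
    rng = np.random.default_rng([seed, _SALT_TREE])
    root_vec = rng.choice([0, 1, 2], p=[0.25, 0.60, 0.15], size=n_kos)
    vectors: dict[int, np.ndarray] = {id(tree): root_vec}
    for node in tree.preorder(include_self=False):
        parent_vec = vectors[id(node.parent)]
        length = node.length or 0.0
        p_event = 1.0 - np.exp(-gain_loss_rate * length)
        events = rng.random(n_kos) < p_event
        steps = rng.choice([-1, 1], size=n_kos)
        vectors[id(node)] = np.clip(parent_vec + steps * events, 0, None)
    ko_ids = [f"K{i:05d}" for i in range(n_kos)]
    ko_table = pd.DataFrame(
        {t.name: vectors[id(t)] for t in tree.tips()}, index=ko_ids
    ).T.astype(int)
    phylogeny = AnnotatedPhylogeny(tree=tree, ko_table=ko_table)
    groups = _partition_genera(phylogeny.tree, genus_size)
    genera = {f"genus{i:03d}": g for i, g in enumerate(groups)}
    if mismatch > 0 and len(genera) > 1:
        names = sorted(genera)
        movable = [(g, leaf) for g in names for leaf in sorted(genera[g])]
        sets = {g: set(genera[g]) for g in names}
        for g, leaf in movable:
            if rng.random() < mismatch and len(sets[g]) > 1:
                target = names[rng.integers(len(names))]
                if target != g:
                    sets[g].discard(leaf)
                    sets[target].add(leaf)
        genera = {g: frozenset(s) for g, s in sets.items() if s}
    taxonomy: dict[str, frozenset[str]] = dict(genera)
    for i, child in enumerate(phylogeny.tree.children):
        tips = frozenset(t.name for t in ([child] if child.is_tip() else child.tips()))
        members = frozenset().union(
            *(genera[g] for g in genera if genera[g] & tips)
        ) if mismatch > 0 else tips
        taxonomy[f"phylum{i:02d}"] = members
    return SyntheticReference(
        phylogeny=phylogeny, taxonomy=taxonomy, genera=genera, newick=newick
    )


def sample_leaf_communities(
    reference: SyntheticReference,
    n_samples: int = 10,
    seed: int = 0,
    *,
    alpha: float = 0.5,
) -> FeatureTable:
    """Dirichlet-distributed phylotype abundances whose features are the
    reference tree's leaves (the ideal-resolution case)."""
    rng = np.random.default_rng([seed, _SALT_LEAF_COMMUNITIES])
    leaves = reference.phylogeny.leaf_names
    abund = rng.dirichlet([alpha] * len(leaves), size=n_samples)
    df = pd.DataFrame(
        abund, index=[f"S{i:04d}" for i in range(n_samples)], columns=leaves
    )
    return FeatureTable(df, feature_kind="taxon", relative=True)


def generate_paired_metagenome(
    taxa_table: FeatureTable,
    phylogeny: AnnotatedPhylogeny,
    leaf_assignment: Mapping[str, str] | None = None,
    *,
    renormalize: bool = True,
) -> FeatureTable:
    """The "measured" metagenome: abundance-weighted mixture of TRUE leaf
    genome vectors (never reconstructed ancestors).

    ``leaf_assignment`` maps each phylotype to its true leaf; by default
    phylotypes are assumed to BE leaf names.  This is the oracle profile
    the inference step is scored against.
    """
    if leaf_assignment is None:
        leaf_assignment = {f: f for f in taxa_table.feature_ids}
    missing = [f for f in taxa_table.feature_ids if f not in leaf_assignment]
    if missing:
        raise ValidationError(f"phylotypes without a true leaf: {missing}")
    ko = phylogeny.ko_table
    rows = [leaf_assignment[f] for f in taxa_table.feature_ids]
    gene_matrix = ko.loc[rows].to_numpy(dtype=float)
    profile = taxa_table.data.to_numpy(dtype=float) @ gene_matrix
    df = pd.DataFrame(profile, index=taxa_table.data.index, columns=ko.columns)
    if renormalize:
        df = df.div(df.sum(axis=1), axis=0)
    return FeatureTable(df, feature_kind="gene", relative=renormalize)


def ancestor_mapping(
    phylogeny: AnnotatedPhylogeny, tiers_up: int
) -> tuple[CladeMapping, dict[str, str]]:
    """Degrade the ideal leaf mapping: send each leaf-phylotype to its
    ancestor ``tiers_up`` levels up (capped at the root).

    Used to measure how inference accuracy decays as phylotypes are
    resolved to ever coarser clades.  Returns the mapping plus the
    identity leaf assignment for scoring.
    """
    mapping = CladeMapping()
    for tip in phylogeny.tree.tips():
        node = tip
        for _ in range(tiers_up):
            if node.parent is None:
                break
            node = node.parent
        mapping.assignments[tip.name] = (node.name, 1.0, 1)
    return mapping, {t.name: t.name for t in phylogeny.tree.tips()}
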