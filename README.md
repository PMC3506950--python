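# phylofunc

Phylogeny-informed functional inference and sparse multivariate
association for microbiome surveys.

16S rRNA surveys tell you *who* is in a microbial community, not *what
they can do*. `phylofunc` bridges that gap for case/control microbiome
studies (its motivating use case is gut dysbiosis in inflammatory bowel
disease): it estimates each sample's gene-family content by mixing
reference-genome annotations along a phylogeny, and then asks which
features — taxa or inferred gene families — track disease, treatment
and environment metadata, with honest multiplicity control.

## The two core methods

**Gene-content inference.** Reference genomes sit on a rooted phylogeny
as leaves, each summarized as a vector of KO (KEGG ortholog) copy
numbers. Ancestral nodes receive distance-weighted averages of their
descendant leaves,

    ĝ = Σ_h w(g,h)·h / Σ_h w(g,h),   w(g,h) = 2^(−dist(g,h)),

so nearby genomes dominate. Each survey phylotype (a named taxonomy
clade, genus and up) is mapped to the tree node maximizing the Jaccard
index of shared descendant genomes, and a sample's KO profile is the
phylotype-abundance-weighted sum of the mapped nodes' vectors.

**Boosted sparse association.** Per feature, with the
variance-stabilized response y = arcsin(√abundance):

    y_i = β₀ + Σ_p β_p X_ip + ε_i,

where the covariates p are chosen by gradient-boosted covariate
selection (additive stumps; a metadatum enters when it is split on in
≥ 1% of 1,000 iterations). Factor levels are Bonferroni-adjusted within
each (feature, metadatum) pair and a global Benjamini–Hochberg step-up
over all records yields q-values; q < 0.25 calls a significant
association. The package reports, per feature kind, the fraction of
features with any significant association — the "function shifts more
than composition" contrast is a first-class output.

Around the core: compositional QC (low-abundance/prevalence filter,
outer-fence outlier masking, imputation), alpha diversity (inverse
Simpson, bias-corrected Chao1, Pielou evenness), a synthetic-data
module with planted ground truth, and a CLI over the whole pipeline.

## Worked example

```python
from phylofunc import (
    BoostedLinearAssociation, GeneContentInferrer, QCPipeline, RunConfig,
    per_sample_spearman, report_summary,
)
from phylofunc.synth import (
    PlantedEffect, generate_annotated_tree, generate_communities,
    generate_metadata, generate_paired_metagenome,
)

# a 200-sample cohort; one phylotype shifted in ulcerative colitis
meta = generate_metadata(200, seed=7)
ref = generate_annotated_tree(n_leaves=50, n_kos=40, seed=7)
taxa, truth = generate_communities(
    meta, 50, [PlantedEffect("G0012", "disease", 0.3, "UC")],
    seed=7, feature_ids=ref.phylogeny.leaf_names,
)

# infer per-sample KO content and validate against the true mixture
inferrer = GeneContentInferrer().fit(ref.phylogeny)
ko = inferrer.transform(taxa)
rho = per_sample_spearman(ko, generate_paired_metagenome(taxa, ref.phylogeny))
print(f"median Spearman rho vs true metagenome: {rho.median():.3f}")

# QC + association at the taxon level
feats, meta_qc = QCPipeline().fit_transform(taxa, meta)
est = BoostedLinearAssociation(config=RunConfig(seed=7)).fit(feats, meta_qc)
hit = est.results_.query("feature == 'G0012' and metadatum == 'disease'")
print(hit[["level", "coefficient", "p", "q"]].round(4).to_string(index=False))
```

Output:

```
median Spearman rho vs true metagenome: 1.000
  level  coefficient      p   q
     UC       0.1910 0.0000 0.0
healthy      -0.0151 0.5131 1.0
```

Phylotypes here are reference-tree leaves, so the inferred metagenome
rank-matches the true abundance-weighted genome mixture exactly
(rho = 1.0). The planted UC shift is recovered with q ≈ 0 — the
coefficient (arcsine-scale shift vs the CD reference group, here 0.19
against a planted 0.3) is attenuated by the zero-clamping and
per-sample renormalization of realized abundances, which is expected
and documented in `docs/methods.md`. The healthy-vs-CD contrast, which
carries no planted effect, is far from significance.

The same pipeline runs from the shell:

```bash
phylofunc --seed 7 run-all --preset assoc-planted --out-dir out/
column -t out/summary.tsv
```

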