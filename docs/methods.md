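# Methods

`phylofunc` implements two methods that together turn a 16S marker-gene
survey plus clinical metadata into statements about microbial *function*
and its covariates: (1) inference of per-sample gene-family (KO)
content from phylotype abundances using a reference phylogeny of
annotated genomes, and (2) a sparse multivariate association of every
feature (taxon, gene or gene set) with mixed-type sample metadata.
This note records the models, the defaults and why, and what the
synthetic benchmarks do and do not establish.

## Functional inference

**Model.** Every reference genome (tree leaf) is a vector of KO copy
numbers (0, 1 or multiple integer copies).  An internal node *g* gets
the weighted average of its descendant leaves *h*:

    g = Σ_h w(g,h)·h / Σ_h w(g,h),     w(g,h) = 2^(−dist(g,h)),

where dist(g,h) is the branch-length path from the node down to the
leaf.  The weight halves per unit of branch length, so reconstruction
is dominated by the closest sequenced genomes, and every reconstructed
value lies inside the [min, max] range of the descendant leaves
(convexity).  The average runs over descendant *leaves*, not
recursively over children; a recursive formulation would re-weight
clades by their internal topology rather than by genome-to-node
distance.

**Clade mapping.** Survey phylotypes are named taxonomy clades, not
tree nodes.  Each clade is assigned the tree node maximizing the
Jaccard index between the clade's genome set and the node's
descendant-genome set.  Ties are broken toward the node with fewer
descendant genomes — the most specific clade consistent with the
optimum — then lexicographically; the number of co-optimal nodes is
recorded.  Clades with zero overlap everywhere are dropped and their
per-sample abundance reported as skipped mass, rather than falling back
to a coarser rank: a fallback would silently mix gene content from the
wrong part of the tree.

**Composition.** Per sample, KO abundance is the abundance-weighted sum
of mapped phylotypes' node vectors.  Output is renormalized to
per-sample relative abundance by default so inferred gene tables flow
through the same QC and association path as taxon tables; rank-based
validation statistics are unaffected by this choice.

**Validation protocol.** Inference is scored by per-sample Spearman
correlation against the "measured" metagenome — the mixture of *true*
leaf genomes.  At ideal resolution (every phylotype is an annotated
leaf) the inferred profile equals the true mixture exactly and rho is
identically 1; forcing phylotypes onto ancestors at increasing depth
degrades the median correlation monotonically.  These two facts are the
acceptance checks; absolute accuracy on real surveys depends on how
well reference genomes cover the community and is not established by
synthetic data.

## Quality control

Defaults follow common practice for compositional survey tables:

- metadata dropped when **> 10%** missing (strict inequality) or
  constant over non-missing entries;
- features dropped when **< 0.001** relative abundance in **≥ 90%** of
  samples (a feature whose median abundance is ≥ 0.001 can never be
  dropped by this rule);
- per-feature outliers outside the outer Tukey fence (quartiles ±
  **3×IQR**, linearly interpolated quantiles — the fence depends on the
  quantile rule, so the rule is recorded in the QC report) are set to
  missing; features with < 4 values or zero IQR are skipped with a
  warning;
- imputation: missing feature cells get the feature's mean across
  samples (a per-sample-mean variant is available via
  `impute_mode="sample"`), missing categorical metadata a dedicated
  `"NA"` level, missing continuous metadata the column mean.

Order: metadata filter → abundance filter → outlier masking →
imputation, so outliers cannot contaminate imputed means.  Masking and
imputation are iterated to a fixed point (imputing an outlier shifts
the feature's quantiles and can expose further cells); iteration stops
when a pass flags nothing, which makes the whole chain idempotent.  A
safety cap of 10 passes guards against oscillation on pathological
distributions.  Every drop, mask and fill is recorded with its reason
in a `QCReport` whose replay on the original input reproduces the
output exactly.

Because mean-imputing masked cells can push a sample's total slightly
above 1, post-imputation tables are no longer declared strictly
compositional.

Responses are variance-stabilized with arcsin(√x), mapping [0, 1] to
[0, π/2]; values above 1 by ≤ 1e-6 are clamped.

## Alpha diversity

Inverse Simpson (1/Σp², the effective number of equally common
features), bias-corrected Chao1 (S_obs + F1(F1−1)/(2(F2+1)), defined
even when no doubletons exist) and Pielou evenness (natural-log Shannon
over ln richness; undefined below two features) are computed per
sample, delegating the arithmetic to scikit-bio.  Chao1 is count-based;
for relative-abundance tables an explicit conversion divides by the
smallest positive value and rounds, making the rarest observed feature
a singleton.  The conversion is off by default in the scalar API and on
in the per-sample table builder (which only ever sees relative data).

## Association engine

Per feature, with y = arcsin(√abundance):

1. **Selection.** y is gradient-boosted on all metadata: 1,000
   iterations of depth-1 regression stumps, squared-error loss,
   learning rate 0.01, 50% row subsampling per iteration, seeded.  A
   metadatum is selected when its columns are split on in at least 1%
   of iterations (dummy columns of one factor pool).  Stumps keep the
   model additive — matching the linear model that follows — and the
   slow learning rate spreads iterations across competing covariates so
   the 1% rule acts as a genuine sparsity filter.  An alternative
   "influence" mode selects on the covariate's share of total
   squared-error gain.  The booster is implemented in-package (a
   seeded numba kernel) because the per-iteration split identity *is*
   the selection statistic; a unit test cross-checks its attribution
   against scikit-learn's gradient booster on planted signals.
2. **Estimation.** Ordinary least squares of y on an intercept plus the
   selected metadata: continuous covariates enter as-is; categorical
   covariates are dummy-coded against their most frequent level (ties
   lexicographic; the reference is recorded per result row).  Aliased
   columns are dropped with a warning.  Per-coefficient two-sided
   t-test p-values come from statsmodels.
3. **Within-factor Bonferroni.** Each level's p is multiplied by the
   factor's number of non-reference levels in the model, capped at 1;
   continuous covariates are unchanged.
4. **Global Benjamini–Hochberg.** One step-up pass over the
   level-adjusted p-values of *all* (feature, metadatum, level) records
   of a run yields q; BH is applied to the Bonferroni-adjusted values
   so the two corrections nest rather than compete.  Records of
   different feature kinds (taxa vs genes) are corrected in separate
   runs, keeping the per-kind significant fractions comparable.

A feature is called significant when any of its records has q < 0.25.
Features for which nothing is selected contribute no records but still
count as tested.  Per-feature boosting seeds derive deterministically
from the run seed and the feature's column position, so a run is
reproducible byte-for-byte and features are mutually independent
given the seed.

Known limitations: OLS on a truncated response ([0, π/2]) is slightly
attenuated for features piled up near zero abundance; inference is
marginal per feature (no mixed effects, no repeated-measures
structure); post-selection p-values are nominal, which the global FDR
step partially absorbs.

## Synthetic data

The generators reproduce the statistical structure the analysis
assumes, with one user seed salted per generator so the streams are
mutually independent.

- **Metadata**: an IBD-style referral cohort — disease status
  (healthy/CD/UC at 12/54/34%), stool-vs-biopsy origin, Gaussian age,
  smoking, and four treatments whose probabilities depend on disease
  (immunosuppressants and steroids concentrated in CD, mesalamine in
  UC), with 5% missingness on age and smoking.  The treatment–disease
  covariation makes the selection problem genuinely confounded, as in
  real cohorts.
- **Communities**: per feature, a lognormal-composition baseline on the
  arcsine scale plus planted linear effects (level indicators for
  categorical metadata, z-scores for continuous) plus Gaussian noise
  (default σ = 0.1), back-transformed through sin² with clamping to
  [0, π/2] and renormalized per sample.  The truth object records the
  planted effects, the latent arcsine-scale matrix, and the
  pre-normalization table, because clamping and renormalization
  slightly attenuate planted effects on the realized abundances.  A
  gamma/Dirichlet-style alternative generator provides a
  model-mismatch robustness check.
- **Reference set**: a Kingman coalescent tree (dendropy) with scaled
  branch lengths; KO copy numbers evolve from a root vector over
  {0, 1, 2} by per-branch ±1 gain/loss events with probability
  1 − exp(−rate·length), so gene content correlates with phylogeny; a
  rank taxonomy is cut from the tree (genus-size clades plus one
  higher rank per root subtree), with optional mismatch noise that
  reassigns genomes between genera.

What passing on this data shows: the algorithms are implemented
correctly, error control holds under the assumed model, and power is
adequate at the stated effect sizes.  What it does not show: robustness
to real 16S artifacts (copy-number variation, chimeras, compositional
coupling between many features, batch effects), none of which the
generators emulate.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: brute-force oracle
comparison on 100 instances (≤ 8 leaves, ≤ 20 KOs, ≤ 5 samples);
Jaccard-vs-exhaustive on 50 toy taxonomies; the degradation experiment
at 5 ancestor tiers × 20 replicates (24-leaf, 30-KO trees); the null
error-control study at 200 features × 10 metadata × n = 200 (50
replicates in the test suite, 20 in the acceptance script); and the
power study at 50 features, β = 0.3, σ = 0.1, n = 200 (50 replicates),
planting on the median-abundance feature so the effect is not hidden
below the low-abundance filter.  These sizes were chosen so each suite
is an honest Monte Carlo check of the property it targets.
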