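# Methods

This note documents the statistical procedure `commclass` implements,
the choices made where the procedure is underdetermined, what the
synthetic generator does and does not emulate, and the limitations a
user should know about.

## Pipeline model and assumptions

The unit of analysis is a genus-level 16S read-count table (samples ×
genera). The pipeline assumes genus-level profiles are informative
enough to separate community configurations — it does not use
phylogeny, OTU/ASV resolution, or strain information.

Two normalisation paths are kept deliberately separate:

* **Clustering path**: counts are divided by the genus's average 16S
  gene copy number and row-normalised to proportions. Copy numbers are
  supplied by the user as a two-column table; genera without an entry
  fall back to a configurable default of 1.0 (neutral scaling) and are
  logged, since no single authoritative copy-number catalogue exists.
* **Diversity path**: raw counts are rarefied (without replacement,
  multivariate hypergeometric) to a common depth — default 1,000 reads —
  before the Shannon index is computed with the natural logarithm.
  Samples below the depth are dropped and logged rather than kept at
  reduced depth, so every retained sample contributes equal
  information.

Bray-Curtis is computed on proportions, not raw counts, so library size
cancels. The root Jensen-Shannon alternative uses a base-2 logarithm so
the distance is bounded by 1 and metric; rows are smoothed with a
pseudocount (default 1e-6, applied before renormalisation) because the
divergence is infinite for disjoint supports.

## Cluster-number selection and refinement

Complete linkage is the default agglomerative criterion because it
produces compact clusters; merge ties follow the linkage
implementation's deterministic ordering, so dendrograms reproduce
between runs. The scan range defaults to k = 2–9. The mean silhouette
width selects k; ties in the merge order or near-ties in the silhouette
(difference < 0.02) set an ambiguity flag listing the competing k
values, since a choice among near-equal silhouettes is a judgement call
rather than a statistical one. Members of singleton clusters receive a
silhouette of 0 (the standard convention).

The refinement pass makes two manual-inspection rules explicit and
auditable:

1. a cluster whose mean silhouette is below the split threshold
   (default 0.2) while some other cluster is high (≥ 0.4) is
   re-clustered at k = 2; the split is accepted when the better of the
   two sub-clusters improves on the parent's mean. This mirrors the
   typical structure of skin-site data: one large tight class plus a
   heterogeneous residue that hides small genuine classes.
2. clusters with fewer than two samples are removed and the remainder
   is re-clustered with the same k-selection procedure, so classes are
   always supported by at least two samples.

Both thresholds and the iteration cap (default 10) are parameters; the
refinement log records every action, and non-convergence raises with
the log attached rather than returning a half-refined solution. Samples
with negative silhouette in the final solution are reported as
outliers, not removed. The refinement cannot be guaranteed to match an
expert's choice on ambiguous data; it encodes the two stated rules and
nothing more.

k-medoids uses the greedy build initialisation plus best-improvement
swaps, with 10 restarts by default (the first deterministic, the rest
seeded-random). The fuzzy clusterer is medoid-based so it can operate
directly on a dissimilarity matrix (a mean-based fuzzy k-means would
require coordinates); membership exponent defaults to 2, hard labels
are argmax memberships, and restarts are selected by the fuzzy
objective.

## Indicator genera

For genus i and cluster c, f_{i,c} is the fraction of cluster-c samples
containing the genus (presence = proportion strictly > 0) and a_{i,c}
is the cluster mean abundance normalised across the K cluster means, so
Σ_c a_{i,c} = 1. The indicator value is d = f·a. Significance comes
from permuting sample labels (default 999 permutations) with each
genus's maximum-over-clusters d as the statistic and the add-one
correction p = (1 + exceedances)/(1 + n_perm), so p is never exactly 0;
the genus-level p attaches to all of that genus's per-cluster scores.
Selection keeps genera with p < 0.01 present in ≥ 50% of at least one
cluster's samples, reporting the best-cluster score per genus ranked by
d.

## Agreement and stability

The Adjusted Rand Index is used for all partition comparisons; it is
chance-corrected, so independent partitions score ≈ 0 regardless of k.
Cross-habitat agreement restricts both habitats to their shared
subjects and, when count tables are supplied, re-clusters each habitat
on that shared subset (re-selecting k by the silhouette scan; a fixed-k
option exists because the choice is defensible either way).
Longitudinal stability pools both visits and clusters them jointly —
this makes the class labels of the two visits directly comparable, at
the cost of assuming the class structure itself is stable across
visits. The transition matrix, maintained fraction (its trace over its
total) and the ARI of paired labels summarise switching.

## Association tests

Categorical factors (gender, location, race/ethnicity, binned BMI:
< 25, 25–< 30, ≥ 30) are tested against class membership by an exact
test of independence: the standard exact routine for 2×2 tables,
exhaustive enumeration of the conditional distribution for larger
tables with total count ≤ 40, and a seeded Monte-Carlo sample of the
conditional distribution (default 100,000 draws, add-one corrected)
beyond that. Continuous factors (age, pH) use one-way ANOVA. Rank-sum
(Mann-Whitney) compares a single taxon's abundance between two groups,
using the exact null distribution when groups are small and untied.
Bonferroni correction is applied within the family of factors actually
tested in one call, and the family size is implicit in the reported
corrected p; the family definition (per habitat report) is a choice —
there is no single canonical family for this design.

## Ordination

PCoA is classical scaling: Gower double-centering of −½D², symmetric
eigendecomposition, coordinates = eigenvectors × √eigenvalue. Negative
eigenvalues (expected for Bray-Curtis, which is non-Euclidean) are
reported but excluded from coordinates; no Cailliez/Lingoes correction
is applied. Axis signs are fixed by making each axis's
largest-magnitude coordinate positive, so output is deterministic.

## Synthetic data: what it emulates and what it does not

Each community class is a Dirichlet over genera with concentration
`base_concentration` everywhere except the signature genus, which gets
`base_concentration × dominance`; samples draw class → composition →
log-normal read depth (median 5,000, σ = 0.5, chosen so rarefaction to
1,000 rarely drops samples) → multinomial counts. This reproduces the
structural features the pipeline relies on — one-genus-dominated
low-diversity classes vs. flat high-diversity ones, class switching
between visits, class-conditional demographics — with exactly known
truth.

Presets: `type_I_vagina_like` (two classes, 85/15 prevalence, dominance
400 — median Shannon ≈ 0.5, silhouette ≈ 0.86), `type_II_stool_like`
(three classes 60/10/30, dominance 25 — Shannon ≈ 2.7, silhouette
≈ 0.33), `type_II_oral_like` (two classes, dominance 4 — Shannon ≈ 3.5,
silhouette < 0.1), and `well_separated` (dominance 500) for recovery
checks. The presets reproduce the qualitative type I/II ordering of
silhouette and diversity.

The dominance parameter drives silhouette up and Shannon diversity down
monotonically for dominance ≳ 10 (the validation sweep uses 10–1,000).
At very low dominance the signature concentration also raises the total
Dirichlet concentration, which evens samples out and can slightly
*raise* entropy — so the monotone regime starts where dominance, not
total concentration, is the leading term.

Not emulated: compositional correlations between genera beyond the
single signature genus, overdispersion beyond Dirichlet-multinomial,
sequencing artefacts (chimeras, contamination), taxonomic
misclassification, subject-level covariate structure, or fitting to
real survey marginals. Passing the recovery tests therefore shows the
pipeline is correct and well-calibrated under its own model, not that
real habitats contain well-separated classes.

## Numerical choices

* Proportion rows must sum to 1 within 1e-9; distance matrices must be
  symmetric with zero diagonal within 1e-9 and are symmetrised after
  validation.
* Silhouette ties (a = b = 0, i.e. duplicated points) give s = 0.
* k-selection ties prefer the smaller k.
* All stochastic operations take an explicit integer seed and use one
  fresh generator per invocation; identical seeds give identical output
  to the byte.
* Validation problem sizes (150 subjects for recovery, 20 seeds for
  recovery rates, 999/299/199 permutations depending on context) are
  chosen so the full battery completes in minutes on one CPU while
  keeping the Monte-Carlo error well below the decision thresholds.

## Known limitations

* Bray-Curtis + complete linkage is one defensible recipe among
  several; the package exposes k-medoids/JSD as the main alternative
  but does not implement model-based (e.g. Dirichlet-multinomial
  mixture) clustering.
* The refinement procedure is a codified heuristic; on data where
  silhouette plateaus are genuinely flat, the ambiguity flag — not the
  chosen k — is the honest output.
* Real-data habitat-level numbers (per-habitat silhouettes, cross-site
  ARIs, switching percentages) depend on cohort and metadata access and
  are outside what the synthetic validation can certify.
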