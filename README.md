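# commclass

Identification and characterization of **community classes** — recurring
genus-abundance patterns, called *enterotypes* in stool — in 16S rRNA
gene survey data, for microbial ecologists working with genus-level
count tables.

Human body habitats host discrete community configurations: a vaginal
sample is usually dominated by *Lactobacillus* or by a mix of anaerobes;
stool samples fall into *Bacteroides*-, *Prevotella*- or
*Ruminococcus*-led groups. `commclass` implements the complete
statistical recipe for finding and characterizing such classes, and a
Dirichlet-multinomial simulator for validating every step against
planted ground truth.

## The method

Starting from a samples × genera read-count table:

1. **Normalisation** — counts are divided by each genus's average 16S
   gene copy number (so multi-copy taxa are not over-counted), then
   row-normalised to proportions y.
2. **Dissimilarity** — Bray-Curtis between samples i and j,
   d(i,j) = Σₖ|y_{ik} − y_{jk}| / Σₖ(y_{ik} + y_{jk}) ∈ [0, 1]
   (root Jensen-Shannon divergence with k-medoids is available as an
   alternative route).
3. **Clustering** — complete-linkage agglomerative clustering of the
   dissimilarity matrix (fuzzy medoids and PAM k-medoids are also
   provided).
4. **Model selection** — the silhouette width
   s(i) = (b(i) − a(i)) / max(a(i), b(i)), where a(i) is the mean
   within-cluster dissimilarity and b(i) the mean dissimilarity to the
   nearest other cluster; the k maximising the mean silhouette over a
   scan (default 2–9) is chosen, and near-ties (< 0.02) are flagged.
5. **Refinement** — clusters with low internal silhouette are split
   when the split improves them, clusters with fewer than two samples
   are removed and the rest re-clustered, and negative-silhouette
   samples are flagged as outliers.
6. **Characterization** — Dufrene-Legendre indicator values
   d_{i,c} = f_{i,c} · a_{i,c} (within-cluster presence frequency times
   share of cross-cluster mean abundance) with permutation p-values,
   filtered at p < 0.01 and ≥ 50% presence; Shannon diversity
   H′ = −Σ pᵢ ln pᵢ on counts rarefied to 1,000 reads; habitat typing
   (type I: median H′ < 1.5 and silhouette ≥ 0.5; else type II).
7. **Agreement** — the Adjusted Rand Index quantifies partition
   agreement across habitats and between visits; longitudinal stability
   pools both visits, clusters jointly, and tabulates class switching.
8. **Visualisation** — PCoA (classical scaling) coordinates of the
   dissimilarity matrix.

## Worked example

```python
from commclass import (bray_curtis, indval, refine_classes,
                       select_indicators, select_k, shannon, to_proportions)
from commclass import synthetic

spec = synthetic.type_II_stool_like(seed=7, n_subjects=120)
table, truth = synthetic.simulate_habitat(spec)

props = to_proportions(table)
d = bray_curtis(props)
sel = select_k(d, k_range=range(2, 10))
sol = refine_classes(d, sel, props)

print(f"chosen k = {sel.chosen_k} (ambiguous: {sel.ambiguous})")
print(f"overall silhouette = {sol.profile.overall:.3f}")
for label, genus in sol.dominant_taxon.items():
    size = int((sol.partition.labels == label).sum())
    print(f"  class {label}: n = {size}, dominant genus = {genus}, "
          f"mean s(i) = {sol.profile.cluster_means[label]:.3f}")

scores = indval(props, sol.partition, n_perm=999, seed=7)
for s in select_indicators(scores)[:3]:
    print(f"indicator {s.genus}: d = {s.d:.3f}, p = {s.p:.3f}")

print(f"median Shannon = {shannon(table, depth=1000, seed=7).median:.3f}")
```

prints

```
chosen k = 3 (ambiguous: False)
overall silhouette = 0.344
  class 0: n = 14, dominant genus = Prevotella, mean s(i) = 0.343
  class 1: n = 33, dominant genus = Ruminococcus, mean s(i) = 0.330
  class 2: n = 73, dominant genus = Bacteroides, mean s(i) = 0.350
indicator Bacteroides: d = 0.932, p = 0.001
indicator Ruminococcus: d = 0.930, p = 0.001
indicator Prevotella: d = 0.920, p = 0.001
median Shannon = 2.678
```

The simulator planted three stool-like classes; the silhouette scan
recovers k = 3, assigns each class its planted dominant genus, and the
three signature genera emerge as the strongest indicators. The moderate
overall silhouette (≈ 0.34) and median Shannon diversity above 1.5 are
the signature of a diverse, diffusely clustered ("type II") habitat.

The same pipeline is available from the shell:

```bash
commclass simulate --preset type_II_stool_like --n 120 --seed 7 --outdir out/sim
commclass cluster  --abundance out/sim/abundance.tsv --seed 7 --outdir out/clu
commclass indicators --abundance out/sim/abundance.tsv \
    --clusters out/clu/clusters.tsv --seed 7 --outdir out/ind
```

Every command writes a `manifest.json` (parameters, seed, input
checksums) from which the run can be reproduced exactly.

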