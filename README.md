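# fosnet

Whole-brain functional-connectome analysis from regional Fos counts, built
for cleared-brain c-Fos imaging studies of brain states such as drug
withdrawal.

Immediate-early gene products like Fos integrate neuronal activation over
roughly 1–2 hours. Counting Fos⁺ cells per atlas-registered brain region and
correlating those counts across subjects yields a *functional connectome*: a
region × region matrix of Pearson correlations whose supra-threshold entries
are functional connections. `fosnet` implements the downstream analysis of
such count tables:

- **Connectome construction** — counts are transformed as log₁₀(x + 1),
  regions correlated across each condition's subjects (Pearson r), and a
  binary network formed from pairs with r > 0.75 (strict, configurable).
- **Module detection** — Euclidean distances between correlation-matrix rows
  feed agglomerative hierarchical clustering (complete linkage by default);
  modules are the subtrees below half the maximum dendrogram merge height.
- **Hub identification** — degree, geodesic betweenness, the
  Guimerà–Amaral participation coefficient
  P_i = 1 − Σ_s (κ_is / k_i)² and the within-module degree z-score;
  hub regions sit in both the top-20 degree and top-20 betweenness lists,
  and high-participation regions are connector hubs.
- **Cholinergic-subsystem statistics** — mean pairwise correlations within
  the basal forebrain cholinergic regions {MA, NDB, SI}, within the
  brainstem–thalamic set {MS, PPN, MH, LH}, and between them (3, 6 and 12
  region pairs), compared by two-way ANOVA (treatment × category, type-II
  sums of squares) with Tukey HSD, plus cholinergic-region × anatomic-group
  correlation profiles and minimal addiction-circuit subnetworks.
- **Gene screen** — each gene's baseline regional expression density
  (percentage of pixels, averaged over in-situ experiments after
  per-experiment centering/scaling) is correlated with the per-region Fos
  log-fold change (difference of group means of log₁₀(x+1)); two-sided
  p-values from the Pearson t-test, t = r·√((n−2)/(1−r²)), are converted to
  q-values by the Benjamini–Hochberg step-up controlling FDR at 5%.
- **Synthetic data with ground truth** — block-correlated log-normal count
  tables (tunable within/between-block correlation and a global-synchrony
  boost for the treatment condition) and expression matrices with planted
  signal genes, so every stage has a recoverable target.

## Worked example

```python
import fosnet as fn

# synthetic two-condition study: 3 planted modules of 20 regions,
# within-module r = 0.9, between 0.1, +0.2 global synchrony under treatment
spec = fn.SyntheticCountSpec(n_regions=60, block_sizes=(20, 20, 20),
                             within_r=0.9, between_r=0.1, global_r_boost=0.2,
                             n_subjects_per_group=40, seed=42)
table, truth = fn.generate_counts(spec)

cfg = fn.RunConfig()                       # r > 0.75, complete linkage, half-height
corr, part = fn.build_connectome(table, fn.CONTROL, cfg)
net = fn.threshold_graph(corr, cfg)
print(part.n_modules, net.n_edges)         # -> 3 570

cent = fn.centrality_table(net, part, cfg)
hubs = fn.identify_hubs(cent, cfg)
```

The control network recovers the three planted modules exactly (adjusted
Rand index 1.0 against the ground truth), and its 570 edges are the three
within-block near-cliques (3 × C(20,2) = 570). Raising the treatment
condition's `global_r_boost` merges modules on average across seeds,
mirroring the decreased modularity seen in withdrawal connectomes (this is
one of the test suite's properties).

The same pipeline runs from the shell:

```sh
fosnet simulate --out sim --seed 42 --within-r 0.9 --between-r 0.1 --n-subjects 40
fosnet connectome sim/counts.csv --groups sim/groups.csv --out conn
fosnet gene-screen expression.csv sim/counts.csv --groups sim/groups.csv --out screen
```

Each command writes its tables plus a `manifest.json` with content checksums;
identical inputs, config and seed reproduce identical checksums.

## Analyzing a published count table

The published withdrawal study's 175-region × 9-subject count table is
distributed as a DOCX supplement; convert it once to
`data/study_fos_counts.tsv` (first column the Allen-atlas acronym, subject
columns named `sal1..sal4` / `nic1..nic5`) and the reproduction checks in
`tests/test_acceptance.py` will verify the published edge counts, module
counts, hub sets and the cholinergic pair ANOVA against it.

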