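# Methods

## Data model and normalization

The raw signal is a region × subject table of Fos⁺ cell counts for two
conditions (control and treatment). Counts are non-negative integers;
missing values are rejected rather than imputed, because the upstream
cell-counting pipelines emit complete tables and imputation would silently
change correlations. At least two subjects per group are required for a
correlation to exist at all; fewer than four triggers a warning, since
Pearson r over three or four subjects is extremely noisy — a real design
constraint of cleared-brain studies, which typically run 4–5 animals per
group.

All analysis happens on the log₁₀(count + 1) scale. The +1 keeps zero counts
finite and maps them to exactly 0; the log tames the several-orders-of-
magnitude spread of per-region counts so that Pearson correlation measures
proportional co-variation rather than being dominated by large regions.

## Connectome and modules

For each condition, the region × region Pearson correlation matrix is
computed across that condition's subjects. Regions with zero variance within
a group (constant counts) have undefined correlations and are excluded with
a logged warning; the zero-variance test uses a relative tolerance of 1e-12
because the log transform of constant integer counts leaves float epsilon in
the variance.

Each region is then embedded as its row of the correlation matrix (unit
diagonal included) and pairwise Euclidean distances between rows drive
agglomerative hierarchical clustering. Complete linkage is the default;
single, average and Ward are selectable because the linkage rule materially
changes half-height module counts and published analyses often leave it
unstated. Modules are the connected subtrees below `cut_fraction` × the
maximum merge height, with `cut_fraction = 0.5` — the half-height cut.
Module ids are renumbered in dendrogram leaf order so that output is stable
across runs. A single retained region forms one module with cut height 0.
Lowering the cut fraction can only split modules, never merge them; the test
suite asserts this monotonicity.

## Networks and centrality

A functional connection is a region pair with r strictly greater than the
threshold (default 0.75). The graph is undirected and unweighted: published
edge counts are cardinalities of supra-threshold pairs, and all hub calls
are rank-based, so binarization loses nothing the analysis uses. Edge
correlations are retained as edge attributes for export only.

- **Degree**: incident edge count.
- **Betweenness**: for every unordered node pair, the fraction of shortest
  paths through the node, summed; unnormalized (no 2/((n−1)(n−2)) factor)
  because only ranks enter hub calls and the raw convention is the simplest
  to audit. Disconnected pairs contribute 0.
- **Participation coefficient**: P_i = 1 − Σ_s (κ_is/k_i)², κ_is the number
  of i's edges landing in module s, computed against the same condition's
  half-height partition (the only partition the pipeline defines). Isolated
  nodes get 0. P_i is bounded by 1 − 1/m for m modules touched.
- **Within-module degree z-score**: the node's within-module degree
  standardized against its module's mean and *population* (n-divisor)
  standard deviation — the Guimerà–Amaral convention used by the Brain
  Connectivity Toolbox and its ports. Constant-degree modules (including
  singletons) give z = 0. Under this convention within-degrees (2, 1, 1)
  standardize to (+1.414, −0.707, −0.707); the sample-sd alternative would
  give (+1.155, −0.577, −0.577) and is deliberately not used.
- **Hubs**: regions in both the top-k degree and top-k betweenness lists
  (k = 20 by default); regions in the top-k participation list are connector
  hubs. Ties with the k-th value are included, so hub sets cannot depend on
  sort order. No numeric participation cutoff is defined here — top-k is a
  pinned convention, not a published rule.

Centrality distributions between networks are compared with a two-sided
Mann–Whitney U test. For samples of ≤20 observations each the p-value is an
exhaustive enumeration over rank assignments, which handles ties exactly
(two identical samples give p = 1); larger samples use the normal
approximation with tie correction and continuity correction. The exact path
agrees with scipy's exact mode whenever scipy supports it (no ties).

## Cholinergic subsystems

Seven long-range cholinergic regions are annotated: MS (Ch1), NDB (Ch2/3),
MA and SI (Ch4), PPN (Ch5), MH (Ch7) and LH. They split into a basal
forebrain subsystem {MA, NDB, SI} and a brainstem–thalamic subsystem
{MS, PPN, MH, LH}. MS is transitional anatomically; it is assigned to the
brainstem–thalamic set here because that assignment yields the 3/6/12
within/within/between pair counts on which the ANOVA's degrees of freedom
(1 and 36 on 42 pair-level observations) depend. The assignment lives in the
metadata table, not in code, so users can move it.

The ANOVA observations are the pair-level raw correlations (no Fisher
transform): 21 pairs per condition across the three categories. Fisher's z
would be statistically tidier but changes the estimand away from "mean R";
raw-r averaging is the field convention for these summaries. Sums of squares
are type-II, so mildly unbalanced layouts (e.g., after region exclusions)
remain well-defined; Tukey HSD runs across all treatment × category cells.
A fully constant response is reported as F = 0, p = 1 for every effect
rather than an epsilon ratio.

The anatomic-group profile gives each cholinergic region's mean correlation
with the member regions of each of the nine major anatomic divisions
(cortical plate, cortical subplate, striatum, pallidum, thalamus,
hypothalamus, midbrain, hindbrain, cerebellum), self-excluded; a region that
is the sole member of its division yields a missing cell. Minimal addiction
networks are induced subgraphs on the cholinergic regions plus a canonical
addiction circuit (ACA, ILA, PL, DP, CP, ACB, BST, BLA, CEA, VTA, IPN),
retaining isolated nodes.

## Gene screen

The per-region Fos log-fold change is the difference of group means on the
log₁₀(x+1) scale (treatment minus control) — equivalently the log₁₀ ratio of
geometric means of (count+1). Regions configured as outliers (the frontal
pole, FRP, by default) are dropped first.

Expression input is long-format (gene, experiment, region, density) with
density on a percentage-of-pixels scale. Each experiment's regional vector
is centered and scaled to unit sd over the shared region set, then a gene's
experiments are averaged — one profile, one test, one q-value per gene.
Z-scoring makes the profile invariant to per-experiment affine rescaling, so
replicate experiments with different dynamic ranges average coherently.
Zero-variance experiments are dropped with a warning; genes left without a
usable experiment are excluded before testing, and the BH denominator counts
testable genes only (untestable hypotheses have no p-value).

Per gene, Pearson r against the LFC over shared regions (≥3 required) gives
a two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df; |r| = 1 is reported as
p = 0. Benjamini–Hochberg step-up q-values (q_i = min over j ≥ rank(i) of
m·p_(j)/j, capped at 1) flag significance at q ≤ `fdr_level` (0.05). The run
log reports the realized |r| significance frontier — the smallest |r| among
significant genes; at the published scale (~174 regions, ~2×10³–2×10⁴
tests) this frontier lands near |r| ≈ 0.23, and BH adaptivity moves it down
as more true signals are planted.

## Synthetic data

The count generator draws latent log₁₀-scale values from a multivariate
normal whose correlation matrix has `within_r` inside blocks, `between_r`
outside, and (for the treatment condition) `global_r_boost` added to every
off-diagonal entry — a planted-module world plus the global-synchrony
phenomenon the pipeline is meant to detect. Counts are
max(round(10^z − 1), 0), inverting the analysis transform so that
log₁₀(count+1) ≈ z and planted correlations survive onto the analysis
scale. The base correlation matrix must be positive semi-definite — an
infeasible spec is a hard error, never silently repaired, because hidden
eigenvalue clipping changes effect sizes; only the boosted treatment matrix
may be eigenvalue-clipped (with a logged warning), since an additive
off-diagonal boost can leave the PSD cone even when the base spec is valid.

Defaults describe a modest cleared-brain study: 60 regions in three blocks
of 20, within/between correlations 0.6/0.1, +0.2 treatment synchrony, five
subjects per group, counts of order 10² cells with log₁₀ sd 0.3 (roughly
2-fold subject-to-subject spread). Test scenarios that need more power
(module recovery at 40 subjects/group, the screen's 150-region/2200-gene
layout) state their sizes explicitly.

The expression generator plants signal genes as ρ·z(LFC) + √(1−ρ²)·noise
(population correlation ρ with the standardized LFC) among independent null
genes; each experiment adds measurement noise with sd `noise_sd` (default
0.1, a small perturbation) and maps affinely onto [0, 100] with ~8σ
headroom, so clipping is rare and correlations are preserved.

What the generator does *not* emulate: integer overdispersion beyond
log-normality, anatomically structured module sizes, negatively correlated
(inhibitory) region pairs beyond what the boost clipping produces, spatial
autocorrelation among expression experiments, and the heavy-tailed
density distributions of real in-situ data. Passing tests therefore
demonstrate correctness of the machinery and its operating characteristics
under the planted model, not performance guarantees on any particular real
dataset.

## Numerical choices and degenerate inputs

- Thresholding is strict (r > threshold); a pair exactly at the threshold is
  not connected.
- Zero-variance regions/experiments/genes are excluded, never imputed, and
  every exclusion is logged.
- Exact-vs-approximate switch for the rank-sum test: enumeration up to 20
  observations per sample (and ≤2×10⁵ combinations), normal approximation
  beyond.
- Dendrogram cut at exactly a merge height joins that merge (scipy's ≤
  criterion); cut heights are fractions of the maximum merge height, so
  exact coincidence is measure-zero for real data.
- Seeds: every generator call takes an explicit seed and builds one local
  `numpy` Generator; nothing touches global RNG state.

## Known limitations

- The half-height module count is sensitive to the linkage rule; the
  configuration exposes it, and reproduction checks against published module
  counts should sweep linkages when the original rule is unstated.
- The participation "high" cutoff is top-k by convention; published analyses
  using a different implicit rule may disagree at the margin.
- The brain-wide cholinergic × anatomic-group ANOVA depends on the exact
  partner-region set; with ambiguous exclusion rules only the direction of
  its treatment effect is a stable target.
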