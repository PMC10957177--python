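# Methods

`fosmap` analyzes brain-wide maps of c-Fos (an immediate-early-gene
product used as a single-cell marker of recent neuronal activation).
The input is a tidy table of c-Fos-positive cell counts per animal and
brain region, with animals assigned to one of four groups — home cage,
isoflurane (ISO), saline injection, ketamine (KET) — in the canonical
design n = 6 / 6 / 8 / 6. From counts the pipeline derives densities
(cells/mm²), screens regions for drug-induced activation against the
matched control group, clusters regions by response profile, infers
per-group functional networks from interregional correlations, and
identifies network hubs. An EEG/EMG module provides the delta/theta
anesthesia-depth metric used to characterize the physiological state.

## Region model and aggregation

Regions live in a three-level hierarchy (6 major divisions → coarse
summary structures → fine areas, Allen-atlas acronyms). Counts are
aggregated to a coarser level by pooling: summed counts over summed
areas. The area-weighted convention is deliberate — density is a
physical ratio, and averaging child densities would weight a tiny
nucleus equally with a large cortical area. Missing child rows are an
error by default; an `ignore` policy aggregates whatever is present,
mirroring the tolerance of gaps that sparse histology data requires.
The bundled `default_ontology.csv` is a convenience subset covering
commonly reported structures, not a complete atlas partition; any valid
ontology table is accepted.

## Activation statistics

All statistics operate on natural-log densities (every reported
statistic — Z, t, r, d — is invariant to the log base).

* **Log-relative density**: ln(density / control-group mean density),
  per treatment animal and region. The control mean is taken on the
  raw density scale (a geometric-mean variant is available); zero
  densities and zero control means yield missing values rather than
  pseudocounts, because downstream summaries already tolerate gaps.
* **Per-animal Z-score**: the animal's ln density standardized by the
  control group's mean and sample SD (n−1) of ln density. A zero
  control SD makes the region's Z-scores missing.
* **Region significance**: the default test (`method="zmean"`) refers
  the mean Z-score to its exact null. Writing z̄ for the mean Z-score
  over n_t treatment animals with n_c controls, under the null of equal
  normal log-densities z̄ / √(1/n_t + 1/n_c) follows Student t with
  n_c − 1 degrees of freedom exactly (the numerator of z̄ is normal and
  independent of the control SD in the denominator). The more obvious
  one-sample t-test of the Z-scores against zero (`method="t"`, also
  provided, with a Wilcoxon signed-rank option and a Shapiro–Wilk-gated
  `auto` mode) is anti-conservative by roughly √2: the Z-scores share
  the estimated control mean, so the treatment-side SD underestimates
  the null SE of their mean. The calibration experiment
  (`fosmap.validation.null_calibration`) makes the difference visible:
  the default test's p-values are uniform on null cohorts and the naive
  test's are not.
* **Multiplicity**: Benjamini–Hochberg step-up at Q = 0.05 over
  regions with a defined p-value.
* **Effect-size screen**: Cohen's d (pooled-SD) on ln densities; among
  significant regions the top ⌈0.40·m⌉ by d are "selected", boundary
  ties included, with deterministic (−d, acronym) ordering. Cohen's d
  is computed on the log scale for consistency with every other
  statistic.
* **Group Z value** (for cluster summaries): mean log-relative density
  divided by its standard error; positive values mean activation above
  control.
* **Co-activation**: the intersection of the two contrasts'
  {q < 0.05 and positive mean log-relative density} sets.

## Response clustering

Features are per-animal log-relative densities (regions × treatment
animals); per-animal profiles, rather than region means, give the
Euclidean metric enough columns to be meaningful and make silhouettes
informative (a `features="mean"` collapse is available for sensitivity
analysis). Missing cells are imputed by the region's row mean, which
preserves the profile's scale without inventing cross-region structure;
all-missing regions are dropped with a warning.

Clustering is agglomerative with complete linkage on Euclidean
distances. Cuts are expressed as a ratio of the maximum merge height
with the convention: *a merge is applied iff its height ≤ ratio × max
height*. Hence ratio 1.0 always yields one cluster, the cluster count
is non-increasing in the ratio, and when all merge heights are equal
(no structure) any ratio < 1 leaves every leaf its own cluster. Cluster
ids are renumbered 1..k in dendrogram leaf order so labels are
reproducible. Ties inside the linkage are resolved deterministically by
passing rows in sorted-acronym order.

Silhouettes use the standard s = (b − a)/max(a, b) with two explicit
degenerate conventions: singleton clusters score 0, and coincident
points (a = b = 0) score 0. The implementation is vectorized in-house
because of those conventions; tests check it against a brute-force
double loop and against scikit-learn on the non-degenerate domain.
Cluster Z-value summaries report mean ± SEM per cluster with a one-way
ANOVA and Tukey HSD across clusters of size ≥ 2.

## Functional networks and hubs

Within each group, Pearson correlations of ln densities across animals
(pairwise-complete, minimum 3 shared animals) quantify co-fluctuation
between regions. Edges require both r ≥ r_min (default 0.82) and a
one-tailed positive-correlation test p < 0.05, using
t = r·√((n−2)/(1−r²)) with n − 2 df. Edge weights are r; isolated
nodes stay in the node set; density is 2|E| / (|V|(|V|−1)).

Modules come from complete-linkage clustering of 1 − r distances cut at
0.7 of the maximum merge height (an absolute-height cut is available;
missing correlations are imputed as r = 0 with a warning).

Centralities: degree is the unweighted edge count; betweenness uses
shortest paths with edge length 1/weight (strong correlation = short
path, the usual brain-connectivity convention; 1 − weight is available)
and the (|V|−1)(|V|−2)/2 normalization with fractional tie-splitting;
eigenvector centrality is the non-negative unit-norm principal
eigenvector of the weighted adjacency of the largest connected
component (zero elsewhere), computed by power iteration. A node is a
**hub** when it reaches the top-(1 − q) rank cut (default q = 0.80,
ties included) in all three measures at once, computed over nodes with
degree ≥ 1; fewer than 5 connected nodes yields no hub calls. The rule
is a documented, configurable operationalization of "scores highly in
all three"; the full ranked centrality table is always emitted so any
other rule can be audited.

## EEG/EMG depth metric

Signals are split into non-overlapping 5-s epochs. Each epoch gets a
Hann-tapered periodogram zero-padded so the bin width is ≤ 0.18 Hz;
band power sums PSD bins with centers in [low, high) — delta 0.5–4 Hz,
theta 6–10 Hz — and the depth metric is their ratio. EMG power is the
per-epoch mean square. Post-administration values are normalized to the
mean of a 5-min pre-administration baseline as log2(value/baseline);
the log-ratio reading is chosen because reported normalized EMG
suppressions below −1 are impossible for a fractional change but
natural on a log2 scale (a `fraction` mode provides value/baseline − 1).

## Synthetic cohorts

The generator plants known structure so every downstream stage is
testable without data access:

* log density = μ_r + log f + Σ_k λ_k F_k + ε, with ε ~ N(0, σ_r²) and
  subject-level factors F ~ N(0, C), C having unit diagonal and
  pairwise correlation `factor_corr`;
* counts ~ Poisson(density × area), area 1 mm² by default so density
  equals count and zero counts (hence zero control SDs) arise
  naturally;
* defaults μ_r ~ U(3, 5) log cells/mm² and σ_r = 0.3 give realistic
  densities (~20–150 cells/mm²) and between-animal variability;
  the canonical group sizes are home cage 6, ISO 6, saline 8, KET 6.

What it does not emulate: anatomical spatial autocorrelation,
segmentation/registration error, or heavy-tailed per-animal artifacts —
so passing recovery tests demonstrate correctness of the inference
machinery under the model, not robustness to histology artifacts.

Two numerical points matter for experiment design. First, Poisson
counting noise adds ~exp(−μ/2) to the log-scale SD, so high-SNR
covariance experiments use μ_r = 8 (~3000 counts) to keep σ_r = 0.1
meaningful, while the effect-recovery experiment uses μ_r = 5 and
σ_r = 0.1, where the raw-scale control-mean convention's lognormal bias
(−σ²/2) and the Poisson log bias stay within ±0.02 of the planted log
fold. Second, a connector hub loading equally on K *independent*
factors has correlation at most 1/√K ≈ 0.707 with members of any one
module — below the effective edge threshold that the one-tailed
α = 0.05 test implies at n = 8 (r ≈ 0.62). Recovering a cross-module
hub therefore requires partially correlated modules, as real functional
networks have; the benchmark plants two 8-region modules with λ = 0.8,
σ_r = 0.1, n = 8 and factor correlation 0.6 (hub–member r ≈ 0.86,
cross-module member r ≈ 0.58) and thresholds that network at
r_min = 0.5. These sizes were fixed by a-priori power analysis of the
planted model.

## Validation experiments

`fosmap.validation` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs, at the sizes used throughout:

* oracle equivalence — betweenness vs all-simple-path enumeration and
  eigenvector vs dense eigendecomposition on 500 random weighted graphs
  of ≤ 8 nodes; silhouette vs a double loop on 200 datasets of ≤ 12
  points; BH q-values vs a direct step-up scan on 10,000 random
  p-vectors;
* null calibration — 1000 null cohorts (201 regions, 6 vs 6): realized
  false-discovery fraction at Q = 0.05 and KS uniformity of pooled
  p-values;
* parameter recovery — planted log-effect 2.0 (σ_r = 0.3, n = 6)
  sensitivity over 200 cohorts; module ARI and hub recovery over 200
  cohorts of the connector-hub design above;
* analytic spot checks — p(r = 0.82, n = 6), atanh(0.82), star-graph
  centralities, and cut-count monotonicity on 1000 random dendrograms.

## Known limitations

* The hub rule's quantile is a convention; different operationalizations
  of "high in all three centralities" can change marginal hub calls.
* Pairwise-complete correlations can produce non-positive-definite
  matrices; the network stage only thresholds entries, so this is
  benign here, but the matrices should not be fed to solvers that
  require definiteness.
* The exact significance test assumes log-normal densities; with heavy
  contamination the Wilcoxon option is the safer (slightly
  conservative) choice.
* Eigenvector centrality on near-disconnected graphs concentrates on
  the dominant component; comparisons of its values across groups with
  different component structure are not meaningful.
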