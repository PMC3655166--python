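# Methods

This note documents the models, parameters and design choices behind
`coexmark`, in the spirit of the methods documentation of statsmodels or
msprime: what each stage assumes, what the defaults mean, and what the
synthetic benchmark does and does not demonstrate.

## Co-expression networks

A network over one expression dataset links genes g, h when the Pearson
correlation of their profiles across samples satisfies PCC(g, h) ≥ τ.
Edges are **signed** by default: strong anti-correlation does not create
an edge, because the downstream selection logic concerns co-up-regulated
disease genes. An `absolute=True` mode admits |PCC| ≥ τ for exploratory
work. Genes with zero variance carry no defined correlation and are
excluded from edge formation with a warning; inference requires at least
3 samples.

**Threshold selection.** The exact τ is a study-level choice, so it is
never hard-coded in pipeline logic. `select_threshold` scans a grid
(default 0.50–0.95 in steps of 0.05) and reports, per candidate, node and
edge counts, density and largest-component coverage; the chosen τ is the
smallest candidate whose density (edges over possible pairs) is at or
below a ceiling (default 1%) — the loosest cutoff that still yields a
sparse, interpretable graph. All diagnostics are exported so the choice is
auditable. The working default elsewhere is τ = 0.8.

**Consensus construction.** Intersection keeps edges present in both
disease networks, with the arithmetic mean of the two weights (any
symmetric combiner would do; the mean is the simplest). Subtraction
removes from the target every edge present in *any* background network;
since edge-level subtraction distributes over union, combining backgrounds
first or subtracting them one at a time gives the same result. A stricter
gene-level mode (`remove_genes=True`) deletes every gene that appears in a
background network; it is off by default because background compendia span
most of the genome and gene-level removal would empty the target — both
behaviours are supported and logged. The concordance filter removes only
genes with genuinely divergent regulation (up in one disease dataset, down
in the other); genes flat in either dataset (|log2 FC| < 0.1) are
retained. The largest connected component is selected by edge count, ties
broken by node count, and reported with its edge-coverage fraction.

## Topology, communities, enrichment

The clustering coefficient uses the unweighted graph; nodes of degree < 2
are reported as C = 0 with a `defined = False` flag. Louvain community
detection also runs unweighted by default (a weight-aware mode is a flag),
with nodes inserted in lexicographic order and a fixed seed so partitions
are reproducible; the reported Q is Newman–Girvan modularity. Enrichment
is a one-sided hypergeometric upper tail P(X ≥ k) per (community, gene
set) over the partitioned gene universe, with k = 0 mapping to p = 1 and
Benjamini–Hochberg correction across all tests performed; only communities
larger than `min_size` (default 20 genes) are tested. Gene sets enter in
GMT format; no annotation database is bundled — collections are user
inputs.

## Marker selection

The tissue route is a conjunction of commuting filters: BH-FDR q < 0.025
with positive fold change in **each** disease dataset separately,
membership in the consensus network, and clustering coefficient ≥ 0.25.
The blood route requires unadjusted p < 0.05 and FC > 0 in blood, mean
blood expression above the 25th percentile of gene-level means (the
per-gene-mean reading of a "lower 25th quantile" exclusion — per-sample
quantiles would be unstable), and positive fold change in both tissue
datasets. Manual literature-curation steps are inherently human judgment
and are represented as allowlist files that intersect a route's computed
output, never computed. The t-test is Welch's by default (group variances
unknown); Student's is a flag. Detectability keeps a gene when its assay
amplified (CT < 40 cycles) in at least 80% of screening samples — the
fraction is configurable since assay panels differ in how strictly they
define a usable transcript.

## ΔΔCt quantification

ΔCt = CT_gene − CT_reference per sample; ΔΔCt subtracts the per-gene
arithmetic mean ΔCt of the control group (a population calibrator, so the
control mean ΔΔCt is exactly zero by construction); RQ = 2^(−ΔΔCt)
assumes perfect per-cycle doubling, which the comparative CT method
presumes. Censored reactions (CT at the 40-cycle run limit) keep their
value as a conservative floor on expression and carry a flag rather than
being imputed, letting downstream consumers exclude them explicitly.
ΔCt is invariant to a constant per-sample CT offset (global efficiency
shifts cancel), and lower gene CT always means higher RQ.

## The classifier ensemble

Preprocessing maps each gene to v' = 1 + 99·(log2 v − min)/(max − min)
with min/max frozen on the training samples; out-of-sample values are
clipped to [1, 100] and a constant training gene maps to 1 with a flag.
The log base is irrelevant — any base rescales log values linearly and
min–max mapping removes linear scale — which the test suite asserts.

Feature selection keeps genes up-regulated in tumors at an uncorrected
t-test p < α (default 0.05), sorted by ascending p. Learner
hyperparameters are deliberately plain and exposed in the API: linear SVM
with C = 1, LDA with pooled covariance, KNN with k = 5 and Euclidean
distance, Gaussian naive Bayes. Cross-validation is stratified 10-fold
(small class sizes make unstratified folds degenerate) with feature
selection refit inside every fold, so reported accuracies are
leakage-free; the no-leakage property is regression-tested by checking
that permuted-label CV accuracy stays near 0.5 at n = 100, p = 51. When a
fold's training part has no feature passing α (expected on null data), the
fold falls back to the single most significant up-regulated gene so CV can
proceed; the public `select_features` itself raises instead, advising a
larger α. The final model is refit on all training data.

The consensus rule is read strictly: a sample with fewer than 2 "control"
votes among the four learners is called tumor, so a 2–2 tie resolves to
control. This sets the operating point of the test and is documented
prominently. The per-sample score is the number of tumor votes (0–4);
"score > 2" is algebraically the same call as the consensus rule, which
resolves the ambiguity of a vote-count-based score in favour of the only
reading consistent with the consensus.

## Evaluation

Contingency metrics with an empty margin are reported as not-available,
never 0. Analyte positivity is strictly greater-than the cutoff: a value
at the upper limit of normal is normal. AUC uses the rank (Mann–Whitney)
identity with midranks for ties — provably equal to trapezoidal ROC
integration, asserted to 1e−12 on tie-free data — and the Hanley–McNeil
standard error. AUC comparison uses the unpaired
Z = (A₁ − A₂)/√(SE₁² + SE₂²), appropriate because the compared cohorts
(PCR validation sets vs the analyte set) are distinct samples. The
call-rate comparison builds the 2×2 (correct, incorrect) × (test A,
test B) table and reports Pearson chi-square both uncorrected (headline)
and with Yates continuity correction, warning when an expected cell drops
below 1. Percentages are offered rounded to integer percent — the
reporting convention of clinical biomarker studies — with raw proportions
always retained.

## The synthetic cohort generator

The generator emulates the statistical shape of a multi-cohort biomarker
study; all sizes and effects below are configuration defaults chosen to
represent that design, fixed once.

* **Expression matrices** live on a log2 intensity scale (per-gene
  baselines ~ N(8, 1.5²), residual noise σ = 0.5) with 50 samples per
  class per dataset. Correlated modules use one latent factor per module,
  x_g = √ρ·z + √(1−ρ)·ε_g, giving exact expected pairwise PCC = ρ
  (default ρ = 0.9, three disease-specific and three generic modules of
  15 genes). Disease modules receive their factor only in the two disease
  tissue datasets; generic modules in every dataset, each dataset drawing
  its own factor.
* **Differential expression**: disease-module genes are shifted by
  δ = 2 log2 units in tumor tissue; 32 designated blood markers are
  shifted by 2 in tumor blood and 0.5 in tumor tissue (so they satisfy the
  blood route's positive-tissue-FC requirement without being network
  members), with blood baselines kept off the expression floor because a
  blood-derived marker is by construction an expressed transcript. Note
  that a shared group shift itself induces correlation, so the empirical
  within-module PCC of DE genes exceeds ρ; the generator's correlation
  calibration is therefore validated with the DE effect switched off.
* **qPCR tables** follow the study's cohort sizes (130 training, 115 and
  120 validation samples): per-gene base CT ~ N(27, 2²), cycle-scale
  Gaussian noise of 0.5 cycles (consistent with reported TaqMan CT
  variability of a few percent), a 2-cycle tumor drop for the 27
  informative genes (a 4-fold change under perfect doubling), a stable
  reference gene with no group effect, and 24 of 75 candidate assays
  planted as failures (censored at 40 cycles) so the detectability screen
  reduces 75 candidates to 51.
* **Comparator analyte**: log-normal per class. The control mean is set
  so 1% of controls exceed the cutoff (19 U/L); the tumor distribution
  has a wider log-sd (1.2 vs 0.5) — a secretory analyte absent in a
  fraction of tumors disperses widely — with its mean set so that 55/81
  of tumors fall below the cutoff. This reproduces the
  elevated-but-overlapping pattern: a clearly significant group
  difference, specificity ≈ 99%, sensitivity ≈ 32%, AUC ≈ 0.6–0.7.

All randomness derives from one seed through spawned generator streams,
so an identical configuration yields a byte-identical cohort.

**What the benchmark does not show.** The generator plants clean Gaussian
structure: no batch effects, no probe-level artifacts, no RNA-quality
covariates, no correlated noise between genes outside planted modules, no
age/sex confounding, and validation cohorts drawn from the same
distribution as training. Passing the recovery and classification tests
demonstrates that the pipeline's logic is correct and leakage-free under
its own assumptions — near-perfect synthetic validation metrics are a
property of the planted effect sizes, not a clinical performance claim.

## Problem sizes and numerical conventions

The default benchmark runs 1000 genes × 100 samples per expression
dataset and the three PCR cohorts above; these sizes keep the full suite
and the acceptance script comfortably fast while leaving every statistic
well-powered. Numerical conventions collected in one place: flat-gene
epsilon |log2 FC| < 0.1; clustering coefficient of degree < 2 nodes is 0
with a flag; hypergeometric k = 0 gives p = 1; BH across all performed
tests; ties in AUC by midranks; Louvain determinism by sorted node order
plus seed; 2–2 vote tie → control; censored CT kept at 40 with a flag;
metric denominators of zero → not-available.

## Known limitations

* The consensus-network route assumes the two disease datasets share an
  identifier namespace; no ortholog or probe mapping is performed.
* Single-reference-gene ΔΔCt; multi-reference geometric-mean
  normalization and standard-curve efficiency estimation are out of scope.
* The AUC comparison is the unpaired form; a paired (DeLong-style) test
  for the same cohort scored by two tests is not implemented.
* Hypergeometric enrichment treats gene sets as flat lists; ontology
  hierarchy and set overlap are ignored.
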