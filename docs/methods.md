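# Methods

This note documents the statistical procedures implemented in
`tmecompare`, the synthetic-data model used to validate them, and the
choices made where the design was genuinely open.  No empirical claim here
goes beyond what the test-suite and `scripts/acceptance.py` themselves
compute.

## Synthetic-data model

`syndata.simulate_counts` draws counts from a gamma-Poisson (negative
binomial) hierarchy:

```
count_cgs ~ Poisson( base_g · boost_{cluster(c),g} · sample_gs · noise_cg · gamma_cg )
```

- `base_g` — lognormal gene baseline (median 3 counts, σ = 1 across genes);
  mitochondrial genes (`MT-` prefix) are elevated 5× and hemoglobin genes
  (`HB` prefix) reduced 5×, so QC fractions take realistic values.
- `boost` — each cluster's marker block is multiplied by `2^marker_logfc`
  (default log₂FC = 2).
- `sample_gs` — per-sample gene-level lognormal random effect (σ = 0.10),
  giving samples their own expression signature.
- `noise_cg` — mean-one lognormal per-cell noise whose σ is
  `cell_sigma × dispersion_by_group[group]` (defaults 0.25 × {PT: 2.0,
  BM: 1.0}).  This is the within-tumor dispersion the heterogeneity
  statistic recovers; the 2:1 PT:BM ratio is the primary planted contrast.
- `gamma_cg` — gamma with shape 1/0.25, the count-level overdispersion of a
  negative binomial with dispersion 0.25.

Cluster assignment is multinomial with group-specific probabilities
(`(1+composition_shift)^k` weights, reversed between groups; shift 0 gives
the exchangeable null used by calibration tests).  Planted ligand–receptor
pairs override the mean of the ligand (receptor) gene to 8.0 in the source
(target) cluster and 0.02 elsewhere.  Default scale is 10 samples per
group × 200 cells × 1,000 genes × 4 clusters — large enough for every
group comparison to have 10 samples per arm while keeping any full pipeline
run in the tens of seconds.

Response cohorts are samples × genes standard-normal matrices in which the
planted informative genes (default 10) are shifted by
`response_effect_sd` (default 2 SD) in responders; labels are balanced.
Bulk survival cohorts tie an exponential hazard to a planted signature:
samples above the cohort-median signature score carry `hazard_ratio` times
the baseline hazard (1/365 per day), with administrative censoring at
1,500 days.

What the generator does **not** emulate: gene-gene correlation beyond
markers and planted pairs, doublets, ambient RNA, batch effects needing
integration, zero-inflation beyond the NB model, or realistic pathway
structure.  Passing tests therefore demonstrate correctness and
calibration of the statistics under a faithful null/alternative structure,
not performance on the full messiness of real tissue data.

## Quality control

Boundary semantics are fixed and tested: the 500–10,000 gene and
1,000–20,000 UMI ranges are inclusive at both ends; the <20% mitochondrial
and <1% hemoglobin fractions are strict.  Both fractions are computed on
UMIs.  Mitochondrial genes are detected by the `MT-` name prefix,
hemoglobin genes by `HB` minus an explicit allowlist of false hits
(`HBEGF`, `HBS1L`, `HBP1`).  Normalization is library-size scaling to
10,000 counts per cell followed by natural-log log1p — the dominant
convention, and the scale every downstream threshold assumes.
Per-gene standardization precedes PCA; requested components are capped at
the matrix rank (with a warning, not an error), and numerically null
trailing components are dropped.  Batch-correction is intentionally out of
scope: the feature matrix is plain PCA, and a precomputed embedding can be
loaded instead (`qc.load_embedding`).

## Markers

The p-value engine is the two-sided Wilcoxon rank-sum (normal
approximation) on log-normalized expression, adjusted by
Benjamini–Hochberg within each one-vs-rest comparison: the substantive
content is the retention rule, not the test, and BH is the field default
where the adjustment is otherwise unspecified.  log₂FC is computed on the
log1p-normalized means with a 1e-9 pseudocount in the ratio.  The
exhaustion-style contrast uses linear-scale fold change ("FC", not log FC)
strictly greater than 1.5 on expm1-scale means, together with an
expressing-fraction difference of at least 0.25 (inclusive).  Clusters
with fewer than 3 cells are skipped and recorded.

## Signature scores

The recovery-curve AUC ranks each cell's genes by decreasing expression
with ties broken by lexicographic gene identifier (reproducibility), and
normalizes the area within the top `top_fraction` window by the best
achievable placement, so scores live in [0, 1].  `top_fraction` defaults
to 0.05, AUCell's published default.  The score is rank-based and exactly
invariant to monotone transforms of a cell's expression — a property the
tests assert bit-for-bit.  Regulon binarization cutoffs are an input (the
SCENIC-style cutoff derivation is upstream, out of scope), with a global
fallback cutoff; activation is `AUC ≥ cutoff`, and cluster significance is
strictly `fraction > 0.20` (`> 0.50` for stromal clusters).  Literature
score lists (Treg, cytotoxicity, proliferation, M1/M2, angiogenesis,
phagocytosis, DC activation/migration/tolerance, HLA-I) ship as an
editable GMT file; they are conventional marker panels, intended to be
replaced by users with curated lists for serious use.

## Heterogeneity

The score is the average Euclidean distance of a sample's cells from a
centroid in PC space.  The wording "all cells" in an intra-tumoral
definition is ambiguous between the sample's own cells and the full
dataset; the default is the sample's own centroid (the standard meaning of
*intra*), with `intra_centroid="dataset"` exposing the other reading.  The
inter-tumoral variant uses the sample's group centroid.  Z-normalization
is applied across samples separately per variant (population SD), and the
group comparison is a two-sided Wilcoxon rank-sum on the per-sample Z
scores.  Single-cell samples score 0 with a warning.  Invariances under
rigid motion and positive homogeneity of degree 1 are asserted in tests.

## Composition

Proportions are reported untransformed to match the per-10,000
presentation convention; a CLR transform is available for users wary of
compositional artifacts.  Sample clustering uses Ward linkage on Euclidean
distances of proportion vectors (the clustering behind such figures is
rarely stated; Ward is the default for compact balanced groups), cut at
k = 2, with agreement = best-matching accuracy against group labels.
Correlation p-values come from the standard Pearson/Spearman nulls;
constant columns are reported as missing rather than zero.

## Ligand–receptor test

The observed statistic for pair (L, R) and ordered cluster pair (A, B) is
the mean of L's average expression in A and R's average in B; multi-subunit
complexes take the minimum subunit average, the convention of the
CellPhoneDB family.  The null shuffles cluster labels over cells
(`n_perm` default 1,000), and `p = (1 + #{null ≥ obs}) / (1 + n_perm)` is
never exactly zero.  The expressing-fraction gate (default 0.10 on both
sides) prevents a pair from being called on near-absent transcripts
regardless of p; gate and α (default 0.05) are parameters.  Interactions
are computed within one group's cells at a time so significant-pair counts
can be contrasted between groups.  Calibration is checked on null data
with the gate disabled (fraction of significant entries within binomial
bounds of α), since the gate deliberately deflates the null rate.

## ssGSEA and survival

The enrichment score walks the decreasing-expression ranking and sums the
difference between the rank-weighted in-set CDF (weights `rank^α`,
α = 0.25, the method's published default) and the unweighted out-set CDF;
α = 0 reduces to an unweighted CDF difference.  Range normalization across
samples is applied when there are ≥ 2 samples and can be disabled.  Bulk
signatures derive from the marker table as the top 30 retained markers
ordered by ascending adjusted p, then descending log₂FC.  The median split
sends ties to the low group (deterministic); the comparison is the
standard two-group log-rank test (lifelines).  Null calibration (uniform p
over simulated null cohorts) and power at hazard ratio 3 are asserted in
the test-suite.

## Response models

LASSO selection is L1-penalized logistic regression with the penalty
chosen by internal stratified cross-validation (AUC scoring) on
standardized features.  The six classifiers use library defaults with the
seed plumbed through; ANN is a single-hidden-layer (16-unit) perceptron —
hyperparameter search is out of scope.  Folds are stratified when class
counts allow, plain otherwise (covers leave-one-out).  Training AUC is
pooled over out-of-fold predictions; orientation is flipped (and recorded)
if it falls below 0.5.  The "most matched combination of two test
cohorts" rule is not well defined in the source workflow; it is
implemented as the best-AUC combination and explicitly labelled
optimistic, with the mean over combinations and the full table always
reported alongside — the honesty property `max ≥ mean` is asserted.
`model_intersection` intersects the gene lists each model actually leans
on (positive importances / nonzero coefficients; all input genes for
KNN/ANN, which expose no importances).

## Problem sizes

The default validation scale is 4,000 cells × 1,000 genes for single-cell
stages, 200-sample bulk cohorts, and 60-sample response cohorts; the
calibration checks use 20 replicate datasets (ligand–receptor), 500 null
cohorts (log-rank uniformity) and 20 permutations/seeds (markers, response
nulls).  These sizes give every asserted property a comfortable margin
while a full test run stays under a minute.

## Known limitations

- The Wilcoxon marker engine ignores sample-level pseudoreplication;
  cells are treated as exchangeable within clusters.
- The permutation null for ligand–receptor tests shuffles labels globally,
  not within samples, so strong sample effects can inflate significance on
  real data.
- ssGSEA and recovery-AUC scores are computed densely; very large atlases
  would need a chunked implementation.
- The generator's independence assumptions make calibration tests cleaner
  than real data would be; see the synthetic-data section.
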