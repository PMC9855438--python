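# tmecompare

Comparative tumor-microenvironment (TME) analytics for grouped single-cell
cohorts, built around a primary-tumor (PT) versus brain-metastasis (BM)
comparison in lung adenocarcinoma.  The package implements, as a tested and
reusable pipeline, the quantitative machinery such a comparison needs:

- **Quality control** — gene filter (expressed in ≥ 10 cells) and the
  four-way cell filter (500–10,000 detected genes, 1,000–20,000 UMIs,
  mitochondrial fraction < 20%, hemoglobin fraction < 1%), followed by
  library-size normalization, log1p, and projection onto the top 100
  principal components.
- **Marker genes** — one-vs-rest Wilcoxon rank-sum per cluster with the
  retention rule *frac_in ≥ 0.25 ∧ log₂FC ≥ 0.25 ∧ p_adj < 0.05* (BH), and a
  heatmap subset requiring an expressing-fraction gap ≥ 0.25; plus contrast
  gene sets (e.g. exhausted vs non-exhausted T cells) at linear FC > 1.5.
- **Signature scores** — per-cell mean scores and an AUCell-style
  recovery-curve AUC: with genes ranked by decreasing expression and window
  `k = ⌈0.05·n⌉`, the score is `Σ_{r≤k} |S ∩ top r|` normalized by its
  maximum `Σ_{r≤k} min(r, |S|)`.
- **Heterogeneity** — per tumor with `m` cells and features `x_ij`,
  `score = (1/m) Σ_i √(Σ_j (x_ij − y_j)²)`, the mean Euclidean distance of
  cells from a centroid `y` (own-sample centroid for the intra-tumoral
  variant, group centroid for the inter-tumoral one), Z-normalized across
  samples and compared between groups by Wilcoxon rank-sum.
- **Regulon rule** — a transcription-factor regulon is significant in a
  cluster when more than 20% of its cells are activated (50% for stromal
  clusters).
- **Composition** — per-sample proportions and per-10,000 rates, Ward
  clustering of samples on proportion vectors cut at k = 2 with PT/BM
  agreement, and type-type proportion correlations.
- **Ligand–receptor tests** — CellPhoneDB-style permutation test:
  statistic = mean of ligand mean in cluster A and receptor mean in cluster
  B (minimum subunit for complexes), null from shuffled cluster labels,
  `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, with an expressing-fraction gate.
- **Bulk validation** — ssGSEA (rank-weighted running-sum, α = 0.25) of
  marker signatures on bulk cohorts, median-split Kaplan–Meier with the
  log-rank test.
- **Response models** — LASSO (L1 logistic, CV-chosen penalty) gene
  selection, then ADB / ANN / GBDT / RFC / XGB / KNN classifiers with
  stratified 5-fold CV, validation AUC, and the per-combination test-AUC
  table whose optimistic "most matched" maximum is always reported next to
  the combination mean.

A synthetic-data module (`tmecompare.syndata`) generates multi-sample count
matrices with cluster markers, mitochondrial/hemoglobin families,
group-specific composition and within-tumor dispersion, planted
ligand–receptor pairs, and binary-response bulk cohorts — so the entire
pipeline runs and is validated without any external download.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (outputs land in `results/`, large intermediates in `scratch/`):

```bash
cd analysis
python 01_simulate_study.py      # 4000 cells x 1000 genes, PT:BM dispersion 2:1
python 02_quality_control.py
python 05_tumor_heterogeneity.py
```

prints, among other things:

```
intra: median z PT +0.99 vs BM -1.03, Wilcoxon p=0.00016
inter: median z PT +1.00 vs BM -1.02, Wilcoxon p=0.00016
intra-inter per-sample Spearman correlation: 0.98
```

i.e. the heterogeneity statistic recovers the planted 2:1 PT:BM
within-tumor dispersion ratio in both variants, and the two variants agree
almost perfectly across samples.  `03_cell_composition.py` reports the
planted composition shift ("most shifted type: C0 (1065 vs 4260 per 10,000
cells, p=0.00016)") and perfect 2-group clustering agreement with PT/BM;
`06_cell_interactions.py` recovers the planted ligand–receptor pair in its
planted direction only (p = 0.000999 forward, non-significant reversed);
`08_response_models.py` shows LASSO recovering 9/10 planted predictive
genes and all six classifiers reaching train CV AUC ≥ 0.9 on the planted
signal.

The same functionality is available as a CLI (`tmecompare simulate|qc|
markers|score|heterogeneity|composition|interact|survival|respond`).

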