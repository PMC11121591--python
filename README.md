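# radgenmap

Radiogenomic mapping for grade-stratified prostate-cancer cohorts: the
package links **MRI texture phenotypes** to **gene-level copy-number
alterations** and asks whether combining the two improves prediction of
clinically significant disease.

It is written for imaging/genomics researchers who have, per patient:

- one masked region of interest (ROI) per MRI modality (T2-weighted and ADC),
- a copy-number segment table (ChAS-style TSV export) with an array QC call
  score, and
- an ISUP Gleason grade group (1 = 3+3, 2 = 3+4, 3 = ≥4+3).

Because real cohorts of this kind are small and rarely shareable, the package
ships a first-class **synthetic-cohort generator** with planted, recoverable
ground truth (group texture differences, grade-linked gene losses, and
calibrated gene–feature correlations), which drives the entire test battery.

## What it computes

**Texture.** Each ROI is min–max normalised to [0, 1], quantised into
*G* = 16 grey levels, and summarised by a grey-level co-occurrence matrix
(GLCM) pooled over the four unit-distance directions, counted symmetrically
and restricted to in-mask pixel pairs. From the normalised GLCM
*p(i, j)* the package computes the 22 classical second-order statistics, e.g.

- Angular Second Moment  Σᵢⱼ p(i,j)²
- Contrast  Σᵢⱼ (i−j)² p(i,j)
- Sum of Squares Variance  Σᵢⱼ (i−μₓ)² p(i,j)
- Inverse Difference  Σᵢⱼ p(i,j)/(1+|i−j|)
- Sum/Difference distribution statistics (Sum Average, Sum Variance,
  Sum Entropy, Difference Variance, Difference Entropy), entropy and
  information measures of correlation,

plus 6 first-order histogram statistics (mean, variance, skewness,
non-excess kurtosis, energy, entropy) — 28 features per ROI, 56 per patient.

**Genomics.** Samples with QC call score < 80% are excluded. Each segment is
called gain (copy number > 2), neutral (= 2) or loss (< 2); abutting
same-state segments are merged; and each gene of the nine-gene panel
(hypoxia: P4HA1, ANGPTL4, VEGFA; androgen: KLK2, KLK3, NKX3.1; apoptosis:
TP53BP2, BAG3, TRAIL.R2) is scored by the signed count of distinct
overlapping events.

**Screening.** Every feature is tested for variability across the three
grade groups — one-way ANOVA when all groups pass Shapiro–Wilk normality,
Kruskal–Wallis otherwise — and kept at p ≤ 0.05 (raw; optional
Benjamini–Hochberg).

**Mapping.** Per grade group and pathway panel, a genes × features matrix of
Pearson r with two-sided p-values, ordered by average-linkage hierarchical
clustering and exported as CSV + annotated heatmap.

**Prediction.** Gradient-boosted shallow regression trees (logistic loss,
depth 2, 200 rounds, learning rate 0.05) classify clinically significant
cancer (grade group ≥ 2) from radiomic, genomic, or combined designs;
evaluation pools out-of-fold scores across cross-validation folds (identical
folds across modes), sweeps the ROC, integrates AUC by trapezoid, and
attaches a stratified percentile-bootstrap confidence interval.

## Worked example

```bash
radgenmap -v run-all --seed 7 --outdir demo_out
```

prints (synthetic cohort of 3 × 30 patients, 64×64 ROIs):

```
INFO radgenmap: simulate: 90 patients -> demo_out/fixtures
INFO radgenmap: extract: 90 patients x 56 feature columns
INFO radgenmap: screen: 45/56 features selected
INFO radgenmap: score-genes: 84 samples retained (QC >= 80%), 6 excluded
INFO radgenmap: map: wrote 9 pathway x grade-group maps
INFO radgenmap: predict: AUCs {'radiomics': 1.0, 'genomics': 0.75, 'combined': 1.0}
pipeline outputs written to demo_out
```

Reading the output: 6 of 90 synthetic arrays fell below the 80% QC call
score and were excluded before gene scoring. Screening found 45 of the 56
features significant (the generator plants strong group texture differences,
e.g. Contrast T2WI, Kruskal–Wallis p = 2.5e-07, and Sum of Squares Variance
T2WI, p = 3.9e-07). `demo_out/maps/` holds the 3 pathway × 3 grade-group
correlation-map grid (CSV r and p matrices plus clustered heatmaps);
`roc_summary.json` reports the cross-validated AUC per design — here the
texture block separates grade groups essentially perfectly (AUC 1.0), the
copy-number block alone is informative but weaker (AUC 0.75 via the planted
grade-linked NKX3.1 losses), and the combined design retains the best
performance. Every artifact is checksummed in `manifest.json`; re-running
with the same seed reproduces it byte for byte.

The same stages are callable individually (`simulate`, `extract`, `screen`,
`score-genes`, `map`, `predict`) on saved intermediates, or directly from
Python via `radgenmap.pipeline.run_all(PipelineConfig(...))`.

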