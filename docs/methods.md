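# Methods

This note documents the models, conventions and design choices behind
`radgenmap`, in the order the pipeline runs them.

## Synthetic cohort model

The generator emulates a three-grade-group prostate-cancer radiogenomics
study: balanced groups (default 30 patients per group), one T2WI and one ADC
ROI per patient, per-sample copy-number segment tables for a nine-gene panel,
an array QC call score, and per-patient ground-truth records.

**Image model.** An ROI is a stationary Gaussian random field: unit white
noise smoothed with a Gaussian kernel of standard deviation
`correlation_length` pixels (default 4), standardised, mixed with white
measurement noise (`noise_sd`, default 0.3 relative to the unit-variance
smooth field), and passed through `tanh(contrast_scale · z)`. Pixel values
are discretised to the 16-bit integer grid so raster fixtures round-trip
losslessly, and the mask is a centred disc covering ≈64% of the frame (an
arbitrary but documented constant). The tanh gain `contrast_scale` is the
texture knob: because every feature is computed after min–max normalisation,
a plain amplitude factor would be invisible, whereas the tanh gain reshapes
the intensity histogram toward the tails and monotonically raises both GLCM
Contrast and Sum-of-Squares Variance (pilot simulation: mean Contrast
2.5 → 22.6 and SSV 9.5 → 47.2 as the gain runs 0.3 → 4.8 at 64×64). Group
defaults (gain 0.7 / 1.1 / 1.6 for grades 1/2/3) plant texture differences
strong enough that screening has real power at 30 patients per group.

**Planted radiogenomic links.** A link (gene, feature, target r) introduces a
patient-level latent driver t ~ N(0,1). On the imaging side the driver
multiplies the tanh gain of the feature's modality by `exp(b·t)` with
b = 0.55 (chosen by pilot simulation; values 0.3–0.8 all give driver–feature
coupling above 0.9, and 0.55 balances dynamic range against tanh
saturation — the measured corr(t, SSV) is ≈0.94–0.97 at image size 64). On
the genomic side the gene's state is a noisy trichotomised copy of the
driver: u = ρ·t + √(1−ρ²)·e, with state +1/0/−1 for u above/between/below
the symmetric equal-thirds normal cutpoints (±0.4307). For that scheme
corr(state, t) = 2φ(c)/√(2Φ(−c)) · ρ ≈ 0.890·ρ, so ρ is set in closed form
(no pilot fitting) to make the population driver–state correlation exactly
the target; targets beyond |r| = 0.890 are rejected with a configuration
error. The end-to-end gene-score ↔ feature correlation is attenuated only by
the driver→feature coupling, so a planted r = 0.7 is recovered at ≈0.65–0.68
(within ±0.1) at 150 patients per group.

**Genomic background.** Non-planted genes gain or lose with probability 0.15
each by default; by default NKX3-1 loss probability additionally rises with
grade (0.10 / 0.45 / 0.65), mirroring the known association of NKX3.1 loss
with aggressive disease, so the genomic block carries grade signal
independent of the imaging block. Segments realising a state cover the gene
locus with random flank jitter; decoy segments are placed ≥10 Mb from any
panel locus. QC call scores follow a truncated normal on [0, 100] (mean 92,
sd 8), so the ≥80% filter excludes ≈7% of samples and its code path is
exercised routinely.

The generator does **not** emulate: 3-D volumes or multi-slice lesions,
scanner artifacts, diffusion physics, spatially localised (non-stationary)
lesions, linkage disequilibrium or segment-length distributions of real
arrays, or inter-gene correlation beyond the planted and grade-linked
structure. Tests that pass on this cohort therefore validate the
*machinery* — feature mathematics, filter and test calibration, recovery of
known effects — not the biological claims one might make on real data.

## Texture features

- Normalisation: masked intensities affinely mapped to [0, 1]; a constant
  ROI maps to zeros with a warning. All downstream features are therefore
  invariant to positive affine rescaling of raw intensities (tested).
- Quantisation: uniform bins over [0, 1]; G = 16 by default; value 1.0
  belongs to the top bin; levels are 1-based.
- GLCM: one matrix pooled over offsets (0,1), (−1,1), (−1,0), (−1,−1) in
  row-major (dy,dx) convention, symmetric counting, and mask-strict pairing
  (both pixels in-mask). Zero valid pairs is an error naming the ROI.
- Catalogue: the 14 classical second-order features plus 8 common extensions
  (autocorrelation, cluster shade/prominence, dissimilarity, maximum
  probability, inverse difference and its normalised variants) = 22; plus 6
  histogram features (64 bins, log base 2, non-excess kurtosis), prefixed
  `Histogram` to keep the 28-name catalogue collision-free.
- Conventions: logs base 2 with 0·log 0 ≡ 0; Sum Variance centred on Sum
  Average (not the historical sum-entropy-centred variant); Difference
  Variance is the variance of the |i−j| distribution; the information
  measures use bit entropies throughout; the maximal correlation coefficient
  is √(second-largest eigenvalue) of the Q matrix restricted to grey levels
  with positive marginal mass.
- Degenerate guards: Correlation and the maximal correlation coefficient
  return 0 (with a warning) when a marginal has zero variance, so the
  28-entry feature vector never contains undefined values.

All 22 features and the pooled GLCM itself are checked against independent
brute-force oracles (explicit pair enumeration; literal-formula
transcriptions) on random small ROIs, and the GLCM against scikit-image on
full-mask input.

## Copy-number scoring

Segment tables use 1-based inclusive coordinates (ChAS-style). Copy number
< 2 / = 2 / > 2 maps to loss / neutral / gain (autosomal baseline; explicit
signed calls pass through). Overlapping or abutting same-state segments of a
sample are merged before counting, making the gene score — signed count of
distinct events overlapping the gene interval — invariant to how a caller
splits one event into contiguous pieces. Scoring is not base-pair-weighted
and mosaic states are not counted fractionally. The bundled panel uses
synthetic toy coordinates (stamped in the panel header) with TRAIL.R2 carried
under its systematic name TNFRSF10B and NKX3.1 under NKX3-1; display names
are preserved for reporting. QC filtering is inclusive at the 80% boundary.

## Screening

Normality is assessed per group with Shapiro–Wilk at α = 0.05 (groups of
fewer than 3 observations route to Kruskal–Wallis, which uses midranks and
the tie-corrected statistic). ANOVA is used only when all three groups pass.
Selection is at raw p ≤ 0.05 with no multiplicity correction by default — an
optional Benjamini–Hochberg switch exists but is off, reflecting the
single-feature reporting style this pipeline reproduces. Constant features
get p = 1, are never selected, and raise a warning. Calibration is tested at
10,000 null features (selection rate 0.05 ± 0.01) and power at a 2-pooled-SD
group shift with 20 per group (≥99% selection).

## Correlation maps

Pearson r between the (discrete) gene score and each feature, per grade
group, with two-sided p-values; cells with zero variance on either side are
set to r = 0, p = 1 and flagged. Display order comes from average-linkage
hierarchical clustering with Euclidean distance on the rows/columns of the r
matrix; single rows/columns keep identity order; r values are never altered.
No correction is applied across the genes × features grid (optional FDR
switch off by default). With real-study group sizes (n = 5) the r estimates
would carry very wide confidence intervals; the package reports every cell
and flags p ≤ 0.05 rather than imposing display thresholds.

## Prediction

The label is clinical significance = grade group ≥ 2 (lesion-volume and
extension criteria are not modelled because synthetic ROIs carry no volume
semantics). The classifier is scikit-learn gradient boosting with logistic
loss, depth-2 trees, 200 rounds, learning rate 0.05 — conservative small-n
defaults, all config-exposed. Cross-validation is stratified k-fold
(shuffled, seeded) or leave-one-out; folds are generated once per comparison
so all modes are evaluated on identical splits, and any fold whose training
part is single-class is merged into its neighbour with a warning. Out-of-fold
probabilities are pooled; AUC is the trapezoid integral of the swept ROC
(identical to the midrank Mann–Whitney statistic, tested to 1e-12); the CI is
a stratified percentile bootstrap (2000 resamples) of the pooled scores; the
interval is widened to contain the point AUC if a resample percentile falls
inside it. Whether a published headline AUC of this design is resubstitution
or cross-validated is generally ambiguous; both are computable here, and all
reported numbers in this package are cross-validated unless stated otherwise.

## Pipeline and reproducibility

One global seed is fanned out to per-stage substreams by SHA-256 hashing of
the stage name, so adding a stage never reshuffles another stage's
randomness; within the generator, per-patient child streams are spawned from
the cohort seed. Every artifact is checksummed into `manifest.json`, and two
runs with the same configuration produce byte-identical manifests (tested,
including rendered PNGs). Fixtures are plain text plus 16-bit PNG; pixel
values are integers by construction so both formats are lossless.

Problem sizes used by the test battery and the acceptance script — 150 per
group for planted-correlation recovery, 10,000 features for screening
calibration, 2,000 simulated maps for the false-positive rate, 50 replicates
for the mode comparison, 30 per group for the end-to-end demo — were chosen
as the smallest sizes at which the statistical tolerances above are
comfortably identifiable.

## Known limitations

- Single representative 2-D slice per modality; no 3-D aggregation.
- The 22-feature catalogue fixes one defensible reading of the classical
  second-order set; other toolkits differ in naming and in the Sum Variance
  and Difference Variance conventions.
- Pearson correlation against a trichotomous gene score is a point-biserial
  style analysis; it is reported as such, not as a rank correlation.
- The boosted model's genomic-only performance is pessimistic at small n
  (depth-2/200-round boosting overfits a 9-column block); the block's signal
  is visible in the single-gene ranking (NKX3-1 alone reaches AUC ≈ 0.8 on
  the default cohort).
- The sex-chromosome copy-neutral baseline is left at the autosomal 2 (none
  of the panel genes need it); a config override exists at the call level.
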