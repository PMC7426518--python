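# Methods

This note documents the models, defaults and numerical choices behind
`texturestager`, and what its synthetic-cohort tests do and do not show
about real imaging data.

## Preprocessing

Each ROI (2D image plus binary inclusion mask) is normalized and
quantized independently. With μ and σ the mean and *population*
standard deviation of the intensities inside the mask, intensities are
clipped to [μ − 3σ, μ + 3σ] and mapped to integer levels by

    q = floor((x − (μ − 3σ)) / (6σ) · N_g),

with half-open bins and a closed top bin (x = μ + 3σ ↦ N_g − 1); a
constant ROI maps to level N_g/2. Because the window is defined by the
ROI's own statistics, the levels — and hence every texture feature — are
invariant to positive affine transforms of the raw intensities, so the
pipeline is insensitive to global scanner gain/offset (but *not* to
nonlinear intensity distortions or bias fields, which are out of scope).

**Gray-level count.** `normalize_quantize` defaults to N_g = 256
(the 8 bits/pixel convention). The pipeline runs at N_g = 32 by default:
on ROIs of a few hundred pixels a 256×256 co-occurrence matrix at
distance 1 is almost empty — nearly every neighbor pair lands in its own
cell, which drives energy toward 1/N_pairs and entropy toward
log₂ N_pairs for *any* texture and erases class contrast. 32 levels keep
the matrices well populated at these ROI sizes while preserving ordering
information. Both entry points expose the level count (`--n-levels`).

## Texture features

Ten features per ROI and sequence. Histogram skewness and kurtosis use
population central moments of the quantized inside-mask levels; kurtosis
is non-excess (normal ≈ 3). Constant ROIs leave them undefined (NaN)
without invalidating the second-order families.

GLCMs are built at distance 1 for the offsets (0,1), (−1,1), (−1,0),
(−1,−1) — angles 0°, 45°, 90°, 135° — counting a pair only when both
pixels are inside the mask, accumulated symmetrically (so 0° ≡ 180°,
standard Haralick practice). Features per matrix: contrast
Σ(i−j)²p(i,j); energy Σp² (the angular second moment itself, not its
square root); entropy −Σp log₂ p; information measure of correlation 1,
(H_XY − H_XY1)/max(H_X, H_Y), defined as 0 when both marginal entropies
vanish. Entropy base (default 2) and the IMC variant (IMC2 available)
are configurable; note IMC1 is ≤ 0 by construction.

GRLMs count maximal constant-level runs along the same four directions;
outside-mask pixels break runs, and each direction's maximal grid lines
(rows, columns, diagonals, anti-diagonals) are traversed once. With the
1-based gray index i = level + 1 (avoiding division by zero at level 0)
and run length j: LRE = Σj²r/N_r, RLN = Σ_j(Σ_i r)²/N_r,
LGLRE = Σr/i²/N_r, SRLGLE = Σr/(i²j²)/N_r.

Each second-order feature is the mean over the directions that contain
at least one pair/run; empty directions (possible on thin masks at
45°/135°) are dropped from the mean rather than zero-filled. This makes
the feature vector exactly invariant under 90° rotations of image and
mask, which the suite verifies.

## Statistical screening

Two-group comparison per feature: each group is first tested for
normality. The default normality gate is the Lilliefors-corrected
Kolmogorov–Smirnov test (the group mean and SD are estimated from the
same data, so plain KS critical values would be anticonservative); the
fully specified KS test is available by flag, as is pooled rather than
per-group assessment. Groups smaller than 4 or with zero variance fail
the gate. If both groups pass, an equal-variance t-test is used (Welch
by flag) and groups are summarized as mean ± SD; otherwise a two-sided
Mann–Whitney U test with median ± IQR summaries. The U test is exact
(permutation distribution) when both groups have ≤ 8 untied values and
uses the tie-corrected normal approximation otherwise. The gate's
overall type-I error is ≈ 5% on null normal data (verified over 1,000
replicates).

Categorical tables use Pearson χ² without continuity correction, or
Fisher's exact test when a 2×2 table has any expected count < 5; larger
sparse tables fall back to χ² with a warning. Spearman correlation with
the binary class uses midranks.

No multiple-testing correction is applied across the 20 features; every
report carries this caveat rather than silently changing the screening
rule.

## Interobserver agreement

ICC(2,1) — two-way random effects, absolute agreement, single measures —
from the two-way ANOVA decomposition:

    ICC = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n),

banded as poor (≤ 0.4), moderate (≤ 0.6), good (≤ 0.8), excellent
(> 0.8). Zero total variance is reported as ICC = 1 with a degeneracy
flag. The estimator recovers simulated reliabilities within ±0.05 at
n = 500 and matches pingouin's ICC(A,1) to 1e-10 in the cross-check.

## Modelling and evaluation

Forward-stepwise logistic regression in the "Forward: LR" style: at each
step the candidate with the smallest likelihood-ratio entry p enters if
p < 0.05; after each entry any included variable with LR removal
p > 0.10 is dropped; iterate to a fixed point. The inner maximum-
likelihood fit is Newton's method (statsmodels) on internally
standardized predictors — texture features live on wildly different
scales (energy ~10⁻², run-length counts ~10³) and raw-scale Newton is
numerically fragile — with coefficients mapped back to original units.
A fit is declared (quasi-)separated, and the candidate flagged and
excluded, when the standardized slope exceeds 15 (odds ratio > e¹⁵ per
SD) or Newton stalls with vanishing deviance; this is the honest
analogue of the infinite coefficients a GUI package would print.

Calibration: Hosmer–Lemeshow over deciles of fitted risk (ties kept in
one bin, zero-expectation bins merged into a neighbor), χ² with
df = bins − 2. Under correct calibration its p-values are approximately
uniform (verified by simulation).

ROC: empirical curve over observed thresholds; AUC by the Mann–Whitney
identity with ties counting ½; 95% CI from the DeLong placement-value
variance; decision direction chosen so AUC ≥ 0.5 and reported as
"> c" / "< c"; operating point maximizing the Youden index, ties broken
toward higher sensitivity; accuracy = (TP + TN)/n at that cutoff.

Evaluation is deliberately **in-sample** — the model is fitted and its
ROC computed on the same cohort, matching how such studies typically
report discrimination. In-sample AUCs are optimistic; the report states
this caveat, and no train/test split or cross-validation is added.

## Synthetic cohorts

The generator emulates the *structure* of a two-reader, two-sequence
tumor-ROI study, not its anatomy. Per subject, a latent Gaussian random
field (white noise smoothed with a class-specific correlation length,
unit variance) is mixed with a per-sequence independent field
(`sequence_coupling`, default 0.6, sets the shared weight), scaled to a
16-bit intensity range (mean 2048, texture SD 512) and degraded with
white noise (default SD 25). The tumor mask is an irregular single
4-connected blob (≥ 64 px) carved by thresholding a separately smoothed
field with a radial taper, covering roughly 15–20% of the frame. The
second reader's mask offsets the signed boundary distance by a smooth
random field bounded by `reader_perturb_radius` (default 2 px), so the
two masks differ only near the boundary (Dice ≥ 0.8 at radius ≤ 2).

Class separation presets set the correlation lengths
(negative/positive): `none` 3/3 (plus equal noise — the null used for
type-I checks), `small` 3/2.2, `large` 6/1.5. A shorter correlation
length means rougher texture: lower GLCM energy, higher entropy — the
direction reported for node-positive tumors. Default cohort size is 50
per class; the discrimination checks use 60/60 at 48×48 px, a size at
which one full pipeline run takes ~2 s, so the 50-replicate simulation
stays inexpensive.

Randomness is hierarchical: every draw derives from
(master seed, subject id, purpose tag) via `numpy` seed sequences, so
identical specs give bit-identical cohorts and enlarging a cohort never
reshuffles existing subjects.

**What passing tests show — and don't.** The synthetic fields are
stationary, Gaussian, isotropic and noise-homogeneous; real tumor MRI
has structured heterogeneity (necrosis, lumen), bias fields, Rician
noise, anisotropic resolution and reader variability far richer than
boundary jitter. Green tests certify the *machinery* — exact matrix
construction, formula correctness, invariances, statistical calibration,
selection behavior — not clinical performance; the in-sample AUC ≈ 1.0
on `large`-effect cohorts reflects the deliberately extreme simulated
separation, not an expected clinical effect size.

## Numerical details and edge cases

* Quantization: values beyond ±3σ saturate at the extreme levels;
  σ = 0 maps to the middle level.
* GLCM probabilities are counts/total per direction; empty directions
  are flagged, never silently zero.
* Logistic fits: Newton, max 100 iterations; a stalled parameter step
  with gradient norm < 1e-6 is accepted as converged.
* Empty stepwise models (no candidate reaches entry) are valid outputs:
  intercept-only, no ROC.
* Constant ROC scores yield AUC 0.5 with an undefined cutoff and a
  degeneracy flag.
* Report JSON contains no timestamps, so identical configs reproduce
  byte-identical reports.

## Known limitations

2D single-slice only (no volumetric features); no GLSZM/NGTDM/wavelet
families; no bias-field or scanner-harmonization stage; no penalized
selection or cross-validation; clinical covariates are accepted in the
label table but not modelled.
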