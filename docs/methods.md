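# Methods

This note records the models, conventions and design choices behind
`radiosurv`, in the order the pipeline applies them.

## Preprocessing

Volumes and masks are NIfTI grids with voxel spacing from the header.
Harmonization follows the study design the package implements: trilinear
resampling of images (nearest-neighbour for masks, preserving binarity) to
isotropic 1 mm voxels with output dimensions `round(dim · spacing)`;
per-volume min-max normalization to [0, 1] (a constant volume maps to
zeros — a defined convention that avoids division by zero); uniform
quantization of in-mask intensities into Ng = 32 equal-width bins spanning
the in-mask min..max range, `level = 1 + floor(Ng·(x − min)/(max − min))`
with the maximum clipped into level Ng. ROI-relative binning (rather than a
fixed [0, 1] range) is the dominant convention for these texture
descriptors. Quantization is monotone by construction; a constant ROI maps
entirely to level 1. The fixed 256×256 in-plane matrix of clinical scans is
deliberately not enforced — only a shared volume/mask grid matters to the
feature math.

## The 45-feature radiomic vector

4 shape + 6 intensity + 19 GLCM + 11 GLSZM + 5 NGTDM features, in a fixed
canonical order. The roster is a documented reconstruction: the descriptor
families are fixed, and the named members include every feature the
screening and integration analyses single out (sum-of-squares variance,
autocorrelation, small-zone/high-gray and large-zone/low-gray emphasis).

* **Shape** — volume (voxel count × voxel volume); surface area by exposed
  voxel-face counting; box-counting fractal dimension (least-squares slope
  of log N(s) against log 1/s over dyadic box sizes, boxes anchored to the
  mask bounding box so the value is translation invariant); porosity =
  (filled − mask)/filled voxels with morphological hole filling.
* **Intensity** — population-form mean/variance/skewness/kurtosis
  (non-excess), energy = mean squared intensity, entropy in bits over a
  32-bin histogram mirroring the gray-level quantization. Constant ROI:
  skewness = kurtosis = 0 by convention.
* **GLCM** — co-occurrences over all 13 unique 3D direction offsets at
  distance 1, each in-mask pair counted in both orders, summed into a
  single symmetric matrix and normalized. The 19 Haralick-family features
  use base-2 logarithms with 0·log 0 = 0; correlation of a single-level
  (degenerate) matrix is defined as 0; difference variance is the variance
  of the |i−j| marginal about its mean.
* **GLSZM** — zones are maximal 26-connected components of equal gray
  level; mass conservation Σ j·s(i, j) = in-mask voxel count holds by
  construction. The 11 standard small/large-zone and low/high-gray
  emphasis statistics are normalized by the zone count.
* **NGTDM** — each in-mask voxel with at least one in-mask 26-neighbour
  contributes |level − neighborhood mean|; coarseness = 1/(ε + Σ pᵢsᵢ)
  with ε = 1e−6, capped at 1e6 for homogeneous ROIs (bounded, testable
  convention); contrast/busyness/complexity/strength follow the standard
  definitions over occurring levels.

Any non-finite feature raises instead of propagating silently. Correctness
is anchored to independent naive brute-force implementations (per-voxel /
per-pair / flood-fill loops) that the test suite runs on dozens of random
ROIs; agreement is at 1e-8 or better. IBSI numerical certification is a
non-goal — oracle equivalence is the correctness bar.

## Univariate survival statistics

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines; rank tests (midrank ties, exact enumeration when the combined
sample is ≤ 10, asymptotic without continuity correction otherwise — which
makes the two-group Kruskal–Wallis and Wilcoxon p-values agree) and the
2×2 Pearson chi-square (no continuity correction) to scipy. The hazard
ratio is exp(β̂) from a single-covariate Cox partial likelihood with
Breslow tie handling, maximized by Newton iteration; SE from the observed
information gives Wald 95% CIs. Monotone likelihoods (complete separation)
are flagged rather than silently reported. The in-package fit is
cross-checked against lifelines' CoxPHFitter in the tests.

Median splits label a patient 1 iff value ≥ median, so ties at the median
go to the high group — the same convention that defines "long-term
survival" as OS at or above the median. Holm–Bonferroni is the step-down
adjustment returned in input order; in the 45-feature screen the
correction family is the full feature roster, and degenerate features
(constant values) are flagged and excluded from the family rather than
aborting the screen.

## Censoring, labels and the integrative model

Censored patients are assigned the mean survival time of uncensored
patients whose time-to-death is ≥ their last follow-up. A censored time
beyond every observed death has no donor set; it keeps its own time (a
documented convention — the rule is otherwise undefined there). An
uncensored-only mode (drop censored patients, no imputation) mirrors the
sensitivity analysis and is available as a pipeline mode.

Outcome labels are a median split of the (imputed) OS. Cross-validation is
stratified 10-fold (plain equal-sized folds risk single-class folds at
n ≈ 70; stratification is the design choice), with a 500-tree random
forest per fold; the headline metric is the mean AUC across folds, with
the pooled out-of-fold AUC reported alongside for transparency. Out-of-fold
probabilities ≥ 0.5 define predicted short/long groups which are then
validated by KM curves and a log-rank test. The train/test protocol fits
on one stratified half and evaluates AUC and predicted-group survival
separation on the other (100/100 at n = 200).

Permutation importance is computed from out-of-bag observations: per tree,
the increase in OOB misclassification after permuting one feature; the
per-feature mean over trees divided by the per-feature standard deviation
of the tree-level increases, averaged across CV folds. Positive values
mark predictive features, values near zero or negative non-predictive
ones. Trees that never use a feature contribute zero increase.

Block integration concatenates radiomic / clinical / genomic /
transcriptomic / protein columns with block provenance tags; therapy type
and other clinical categoricals are one-hot encoded (the encoding used in
the original analysis is unstated; indicators are the neutral choice);
patients missing a requested block are dropped with a logged count. The
transcriptomic block is pre-screened per gene by median-split log-rank at
raw p < 0.05 — a deliberately uncorrected univariate filter (threshold
configurable).

## Synthetic cohorts

The generator emulates the study conditions so downstream stages can be
tested with known ground truth:

* **Lesions** — ellipsoidal masks (semi-axis factors 1.0/0.9/0.8) inside
  48³ volumes at 1 mm spacing; in-mask intensities are a Gaussian random
  field whose correlation length (`texture_scale_mm`, drawn per patient
  from 1–6 mm) is produced by Gaussian smoothing of white noise, rescaled
  into (0.1, 1]; background is uniform noise in [0, 0.02]. An infinite
  texture scale yields a perfectly uniform interior (the constant-image
  limit). The correlation length links monotonically to texture features:
  coarseness rises and GLCM contrast falls as the field smooths.
* **Tables** — age ~ N(62, 10) clipped to 18–84, KPS on the routine
  40–100 scale, therapy type RT+TMZ/RT/none (0.6/0.28/0.12), 100 mutation
  genes with prevalences U(0.05, 0.4) (the first named after recurrently
  mutated GBM genes), standard-normal expression, and six IHC proteins
  (Ki67, EGFR, PTEN, CD44, p53, vimentin) scored on the routine ordinal
  0–3 scale and treated as numeric.
* **Survival** — exponential event times with hazard
  h·exp(Σ βᵢzᵢ), baseline h = 1/400 days⁻¹ (median OS ≈ 0.75 years,
  GBM-like); continuous planted features enter z-scored, binary mutations
  as 0/1 so their β is a per-carrier log hazard ratio. Censoring is an
  independent exponential whose rate is solved numerically so the expected
  censored fraction matches the target (default 0.10, the order of the
  ~5% censoring in the cohorts the design mirrors). Censoring therefore
  stays non-informative — the assumption behind the imputation rule.
  Note that with planted effects the censoring *flag* still correlates
  with hazard (high-risk patients die before censoring); independence of
  the censoring *time* is what the design guarantees.
* **Determinism** — all randomness derives from one seed via spawned
  child sequences; NIfTI files are gzip-compressed with mtime pinned to 0,
  so reruns are bit-identical.

The default planted configuration used by the examples and the acceptance
script is one protective radiomic effect (−log 3 per SD of GLCM
sum-of-squares variance, echoing the protective direction reported for
that feature) and one deleterious mutation (log 2.5 for `mut_CIC`).

What the generator does **not** emulate: MR physics (bias fields, noise
spectra, multi-sequence contrast), multifocal or irregular lesion
morphology, linkage disequilibrium or co-expression structure, and
covariate-dependent censoring. Passing tests therefore demonstrate the
statistical machinery is correct and recovers planted signal under the
stated model — not that the pipeline's clinical numbers transfer to real
cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script run cohorts of 24–200 patients with
32³–48³ voxel volumes, 500-tree forests for headline metrics and smaller
forests for ancillary property checks; simulation replicate counts
(20–500) are chosen so each check's sampling error is well inside its
assertion band. Newton iteration for the Cox fit starts at β = 0,
converges at |Δβ| < 1e−10, and aborts with a flag when the likelihood is
monotone (|β| > 20). The transcriptome-screen power test plants 10
prognostic genes rather than 20 because many simultaneous hazard effects
act as frailty that attenuates each gene's marginal signal.

## Known limitations

* The 45-feature roster is a reconstruction of the named descriptor
  families, not a certified list.
* Porosity depends on the hole-filling operator's connectivity
  (scipy default); fractal dimension depends on the dyadic box sizes used.
* The chi-square comparison of two models' AUCs is operationalized as the
  2×2 table of correct/incorrect predictions on shared test patients — an
  interpretation, since the construction behind the published comparison
  is not specified.
* Survival times are exponential (constant hazard); real GBM hazards are
  time-varying. This is intentional: parameter recovery is analytically
  checkable under the exponential model.
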