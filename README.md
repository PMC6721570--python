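# radiosurv

Radiomic and multi-omic survival modelling for IDH1 wild-type glioblastoma
(GBM) cohorts.

Molecular predictors alone explain little of the survival variation in IDH1
wild-type GBM. This package implements, as a tested and reusable library, a
pipeline that quantifies tumor phenotype from contrast-enhanced T1 MRI as a
45-feature 3D radiomic vector, screens each feature for prognostic value,
and integrates radiomic, clinical, gene-mutation, gene-expression and IHC
protein blocks in a random-forest classifier of short- vs long-term overall
survival (OS). Because the original patient cohorts are not redistributable,
the package ships a first-class synthetic-cohort generator with planted
proportional-hazards effects, so every stage is verifiable end to end.

## What it computes

**Radiomics.** Volumes are resampled to isotropic 1 mm voxels, min-max
normalized to [0, 1], and ROI intensities uniformly quantized to
Ng = 32 gray levels. From the quantized ROI the package computes
4 shape, 6 intensity, 19 GLCM, 11 GLSZM and 5 NGTDM features (45 total).
The GLCM is the symmetric normalized matrix p(i, j) over the 13 unique
distance-1 3D offsets; e.g. sum-of-squares variance is
Σᵢⱼ (i − μₓ)² p(i, j) and autocorrelation Σᵢⱼ i·j·p(i, j). GLSZM zones are
26-connected components of equal gray level; NGTDM accumulates per-level
deviations from in-mask neighborhood means.

**Univariate screen.** Each feature is dichotomized at its cohort median;
groups are compared by the log-rank test; the hazard ratio
HR = exp(β̂) with 95% Wald CI comes from a single-covariate Cox partial
likelihood (Breslow ties, Newton iteration); p-values are Holm–Bonferroni
corrected across the 45-feature family.

**Integrative model.** Censored patients are assigned the mean survival of
uncensored patients who lived at least as long; labels are short/long OS at
the median of the (imputed) times; a 500-tree random forest is scored by
stratified 10-fold cross-validated AUC and by a held-out train/test split
(100/100 at n = 200), with predicted groups validated by Kaplan–Meier
curves and a log-rank test. Feature relevance is out-of-bag permutation
importance, normalized by the per-feature standard deviation of tree-level
error increases.

## Worked example

`examples/04_integrative_model.py` generates a 200-patient synthetic cohort
with one protective radiomic effect (log-HR −log 3 per SD of GLCM
sum-of-squares variance) and one deleterious mutation (log-HR log 2.5 for
`mut_CIC` carriers), then runs the 100/100 protocol:

```
integrated table: 200 patients x 155 features
median-OS cutoff: 204 days
held-out AUC: 0.747
log-rank p between predicted groups: 4.36e-07
```

The AUC of 0.747 means the forest ranks a random long-term survivor above a
random short-term survivor ~75% of the time on unseen patients; the
log-rank p confirms the two predicted groups have genuinely different
survival curves. On a null cohort (no planted effects) the same pipeline
returns AUC ≈ 0.5 — there is no leakage. The other examples cover cohort
simulation, single-lesion feature extraction, the univariate screen, and
the demographics table.

A thin CLI mirrors the library (`radiosurv simulate | extract | screen |
fit-cv | fit-holdout | report | run-all`).

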