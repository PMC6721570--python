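"""Generate a small synthetic GBM-like cohort and look at what it contains.

Each patient gets a textured ellipsoidal lesion (the texture correlation
length varies between patients), clinical covariates, a binary
gene-mutation matrix, gene expression, IHC protein scores, and a survival
time drawn from a proportional-hazards model with a planted radiomic and a
planted genomic effect.
"""

from radiosurv import CohortConfig, default_planted_effects, generate_cohort

config = CohortConfig(
    n_patients=30,
    volume_shape=(32, 32, 32),
    lesion_radius_range_mm=(7.0, 11.0),
    n_mutation_genes=20,
    n_expression_genes=30,
    planted_effects=default_planted_effects(),
    seed=7,
)
cohort = generate_cohort(config)

print("planted log-hazard effects:", config.planted_effects)
print("\nclinical table (first 5 patients):")
print(cohort.clinical.head())
print("\nradiomic feature matrix:", cohort.radiomics.shape)
print("mutation matrix:", cohort.mutations.shape,
      "| expression:", cohort.expression.shape,
      "| proteins:", cohort.proteins.shape)
frac_cens = 1 - cohort.clinical["event"].mean()
print(f"\ncensored fraction: {frac_cens:.2f} (target {config.censoring_rate})")
print("A patient's survival hazard rises with the planted mutation and "
      "falls with higher GLCM sum-of-squares variance.")
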