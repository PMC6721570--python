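"""Integrative short- vs long-survival classification.

Censored survival times are imputed, patients are labelled short/long at
the median OS, the radiomic + clinical + genomic + protein blocks are
concatenated, and a 500-tree random forest is evaluated on a held-out half
of the cohort (the 100/100 protocol at n = 200).
"""

from radiosurv import (
    CohortConfig, default_planted_effects, generate_cohort,
    integrate_blocks, make_outcome, train_test_eval,
)

cohort = generate_cohort(CohortConfig(
    n_patients=200, planted_effects=default_planted_effects(), seed=13,
))
labels = make_outcome(cohort.records)
table = integrate_blocks(
    radiomics=cohort.radiomics,
    clinical=cohort.clinical[["age", "therapy_type"]],
    genomics=cohort.mutations,
    proteins=cohort.proteins,
)
result = train_test_eval(
    table, labels, records=cohort.records,
    test_size=0.5, n_trees=500, seed=3, compute_importance=True,
)

print(f"integrated table: {table.n_patients} patients x "
      f"{table.data.shape[1]} features")
print(f"median-OS cutoff: {labels.cutoff_days:.0f} days")
print(f"held-out AUC: {result.mean_auc:.3f}")
print(f"log-rank p between predicted groups: {result.extras['logrank_p']:.2e}")
print("\ntop features by normalized OOB permutation importance:")
print(result.importances.sort_values(ascending=False).head(8).round(3))
print("\nAn AUC well above 0.5 plus a small log-rank p shows the model "
      "separates short- from long-term survivors on unseen patients; the "
      "planted radiomic and genomic drivers should rank near the top.")
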