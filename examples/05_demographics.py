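"""Demographics summary of a clinical table.

Counts and percentages per stratum; percentages are truncated (not
rounded) to two decimals, e.g. 129/132 = 97.727% prints as 97.72.
"""

from radiosurv import CohortConfig, generate_cohort, cohort_summary

cohort = generate_cohort(CohortConfig(
    n_patients=132, with_images=False,
    n_mutation_genes=10, n_expression_genes=10, seed=2,
))
summary = cohort_summary(cohort.clinical)
print(summary.to_string(index=False))
print("\nWithin each variable the stratum counts sum to the cohort size; "
      "survival bands report their censored counts in parentheses.")
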