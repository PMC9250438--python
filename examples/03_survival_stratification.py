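"""Stratify simulated survival by PTPRT alteration status.

The simulator assigns module-altered samples a doubled event hazard
(hazard ratio 2.0 on a 0.02/month exponential baseline) under uniform
censoring.  This example recovers that separation: Kaplan-Meier medians
per group and the log-rank test on the altered vs wild-type split.
"""

from metamod import (
    SimConfig,
    assign_cohorts,
    build_mutation_matrix,
    group_by_alteration,
    km_estimate,
    logrank_test,
    mutation_records_from_frame,
    sample_records_from_frame,
    simulate_cohort,
    simulate_survival,
    split_groups,
)
from metamod.survival import SurvivalRecord

config = SimConfig(seed=40)
clinical, mutation, truth = simulate_cohort(config)
survival_frame = simulate_survival(config, truth)

samples = sample_records_from_frame(clinical)
mutations = mutation_records_from_frame(mutation)
matrix = build_mutation_matrix(mutations, samples, assign_cohorts(samples), config.cancer_type)

records = [
    SurvivalRecord(str(r.SAMPLE_ID), float(r.TIME_MONTHS), bool(r.EVENT))
    for r in survival_frame.itertuples(index=False)
]
labeled = group_by_alteration(matrix, ["PTPRT"], records)
altered, wild = split_groups(labeled)


def median_time(curve):
    for t, s in zip(curve.event_times, curve.survival):
        if s <= 0.5:
            return t
    return float("nan")


km_alt, km_wt = km_estimate(altered), km_estimate(wild)
res = logrank_test(altered, wild)

print(f"altered n = {len(altered)}, wild-type n = {len(wild)}")
print(f"KM median survival: altered {median_time(km_alt):.1f} months, "
      f"wild-type {median_time(km_wt):.1f} months")
print(f"log-rank chi2 = {res.chi_square:.2f}, P = {res.p_value:.3g}")
print()
print("with a true hazard ratio of 2 the altered median should be roughly")
print("half the wild-type median and the log-rank P far below 0.05.")
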