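"""Survival analyses around a prognostic gene: KM, Cox, attenuation.

Dichotomises the planted driver's expression at the cohort median, then
walks through the survival machinery: Kaplan-Meier curves per group, the
log-rank test, univariate and multivariate Cox fits, and the additive
one-covariate-at-a-time attenuation table.
"""

import numpy as np

from nbscreen import SimulationConfig, simulate_cohort
from nbscreen import diffexpr, survival

cohort = simulate_cohort(SimulationConfig(seed=1))
driver = cohort.truth.driver_gene
expr = diffexpr.log2_normalized(cohort.counts)
labels = survival.dichotomize_by_median(expr.loc[driver].to_numpy())
times = cohort.clinical["os_time"].to_numpy()
events = cohort.clinical["os_event"].to_numpy()

for name, mask in (("low", labels == 0), ("high", labels == 1)):
    km = survival.km_estimate(times[mask], events[mask])
    print(f"{name}-expression group: S(1500 d) = {km.survival_at(1500):.3f}")

stat, p = survival.logrank_test(times, events, labels)
print(f"log-rank: chi2 = {stat:.2f}, p = {p:.2e}")

uni = survival.cox_fit(labels[:, None].astype(float), times, events)
print(
    f"univariate Cox: HR = {uni.hr[0]:.2f} (planted {cohort.truth.driver_hr}), "
    f"Wald p = {uni.wald_p[0]:.2e}"
)

multi = survival.multivariate_cox(labels, cohort.clinical)
print("\nmultivariate Cox (gene + stage + age + MYCN status):")
for name, hr, p_w in zip(multi.names, multi.hr, multi.wald_p):
    print(f"  {name:16s} HR = {hr:5.2f}  p = {p_w:.3f}")

table = survival.additive_cox_attenuation(labels, cohort.clinical)
print("\nadditive attenuation (covariates ranked by impact on the gene HR):")
print(table.round(3).to_string(index=False))
print(
    "\nStage, age and amplification are generated independently of survival\n"
    "here, so the gene HR barely moves; with a real confounder the top row\n"
    "would show a large delta_hr."
)
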