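"""Compare subphenotypes on covariates and 28-day survival.

Builds a Table-1-style comparison (chi-square/Fisher for categorical,
t-test/ANOVA or Mann-Whitney/Kruskal-Wallis for continuous, chosen by a
normality screen), Kaplan-Meier curves to 28 days and the log-rank test.
"""

from sofatraj import (
    CohortConfig, generate_cohort, km_estimate, logrank_test,
    outcomes_to_survival, summarize_groups, survival_at,
)
from sofatraj.characterization import comparisons_to_frame

cohort = generate_cohort(CohortConfig(n_patients=1000, seed=17))
labels = cohort.truth_labels

comparisons = summarize_groups(cohort.covariates, labels)
print(comparisons_to_frame(comparisons)[["variable", "test", "statistic", "pvalue"]]
      .round(4).to_string(index=False))
# Each row reports the omnibus test across the four archetypes; p < 0.05
# flags covariates whose distribution differs between subphenotypes.

survival = outcomes_to_survival(cohort.outcomes, labels)
km = km_estimate(survival)
print("\n28-day survival by archetype:")
for group, s in sorted(survival_at(km, 28.0).items()):
    print(f"  {group}: {s:.3f}")
stat, p, df = logrank_test(survival)
print(f"\nlog-rank chi2 = {stat:.1f} (df={df}), p = {p:.2e}")
# RW has the lowest survival and RI the highest, mirroring the mortality
# gradient the archetypes were generated with; the log-rank test rejects
# equality of the four survival curves.
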