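"""Predict subphenotype membership from early data, with Shapley attribution.

Trains a random forest on features available at 6 h and 24 h after ICU
admission (demographics, comorbidity, ventilation, per-organ SOFA
subscores and worst lab/vital values, all strictly before the cutoff) and
explains individual predictions with Monte-Carlo permutation Shapley
values.
"""

from sofatraj import (
    CohortConfig, build_feature_snapshot, generate_cohort, shapley_attribution,
    train_classifier,
)
from sofatraj.prediction import accuracy_over_time

cohort = generate_cohort(CohortConfig(n_patients=1500, seed=9))
labels = cohort.truth_labels

reports = accuracy_over_time(
    cohort.measurements, cohort.covariates, labels, times=(6, 24), seed=9
)
for r in reports:
    print(f"t = {r.cutoff_hour:>2} h: accuracy {r.accuracy:.3f} "
          f"(95% bootstrap CI [{r.ci_low:.3f}, {r.ci_high:.3f}], n_test={r.n_test})")
# Accuracy rises from 6 h to 24 h as the trajectories diverge — the
# subphenotypes become easier to predict with more of the stay observed.

snapshot = build_feature_snapshot(cohort.measurements, cohort.covariates, 6)
trained = train_classifier(snapshot, labels, seed=9)
attrib = shapley_attribution(
    trained,
    snapshot.X.loc[trained.test_ids[:10]],
    snapshot.X.loc[trained.train_ids],
    n_permutations=100,
    seed=9,
)
print("\ntop features by mean |Shapley value| (10 explained patients, 6-h model):")
print(attrib.mean_abs.head(8).round(4).to_string())
# A positive Shapley value pushes the predicted-class probability up for
# that patient; the ranking shows which early features carry the
# subphenotype signal (organ subscores dominate).
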