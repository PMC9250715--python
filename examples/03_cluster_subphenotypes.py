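"""Derive trajectory subphenotypes: DTW distances + hierarchical clustering.

Computes the pairwise dynamic-time-warping distance matrix over total-SOFA
trajectories, clusters it with average-linkage HAC, cuts at k=4, names the
clusters from their mean-curve slopes, and reports recovery of the known
archetypes plus the cluster-count index ensemble.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from sofatraj import (
    CohortConfig, build_trajectories, cut_tree, generate_cohort, hac_linkage,
    label_archetypes, pairwise_dtw, select_k,
)

config = CohortConfig(
    n_patients=400, noise_sd=0.5, missing_rate=0.0, full_missing_rate=0.0, seed=1
)
cohort = generate_cohort(config)
traj, _ = build_trajectories(
    cohort.measurements, cohort.covariates, patient_ids=cohort.patient_ids
)

distances = pairwise_dtw(traj)
tree = hac_linkage(distances, linkage="average")
assign = cut_tree(tree, 4, patient_ids=list(traj.index))
labeling = label_archetypes(assign, traj)

ari = adjusted_rand_score(cohort.truth_labels.to_numpy(), assign.clusters)
print("cluster sizes:", np.bincount(assign.clusters)[1:].tolist())
print("cluster -> archetype:", labeling.labels)
print(f"adjusted Rand index vs truth: {ari:.3f}")
# ARI near 1 means DTW+HAC recovered the generating archetypes almost
# perfectly at this noise level.

report = select_k(distances, tree=tree)
print("\ncluster-count indices (silhouette/Dunn max, C-index min):")
print(report.table.round(3).to_string())
print("votes:", report.votes, "-> chosen k =", report.chosen_k)
# Note the geometry: RW sits much farther from the other three archetypes
# than they sit from each other, so these indices prefer the coarse
# RW-vs-rest split (k=2) even when the four clusters are clean — the
# within-cluster dispersion column still shows a sharp elbow at k=4.
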