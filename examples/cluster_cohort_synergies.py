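"""Cohort-level synergy clustering: the full pipeline on 10 subjects.

Pools every subject's retained PCs, clusters them by the angle between
loading-vector lines (complete linkage), cuts the dendrogram at the largest
merge-height gap and selects the synergies covering >= 80% of the pool.
"""

import numpy as np

import synkin

gt = synkin.make_ground_truth(K=4, seed=3, prevalence=[1, 1, 0.6, 0.4])
recs, _ = synkin.simulate_cohort(gt, n_subjects=10, n_grasps=12, n_repetitions=4, seed=3)

pcsets, catalog = synkin.run_study(recs, threshold=0.8)

summary = synkin.cohort_summary(pcsets)
print(f"retained PCs per subject: {summary.k_counts}")
print(
    f"variance explained: {100 * summary.variance_mean:.2f}"
    f" +/- {100 * summary.variance_sd:.2f} % (mean +/- SD over subjects)"
)
print(
    f"pooled {sum(p.k for p in pcsets)} PCs -> {len(catalog.clusters)} clusters "
    f"at cut {catalog.cut_distance:.1f} deg"
)
for i, c in enumerate(catalog.clusters):
    mark = "*" if i in catalog.selected else " "
    print(
        f" {mark} cluster {i}: {100 * c.variance_fraction:5.1f}% of PCs, "
        f"{c.n_pcs} PCs from {c.n_subjects} subjects"
    )
print(f"selected synergies (cumulative >= 80%): {catalog.selected}")

# Starred clusters are the cohort-level synergies; a cluster's variance
# share is its PC count over the pooled total, and its prevalence is the
# number of distinct subjects contributing at least one PC.
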