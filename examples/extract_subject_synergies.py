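"""Per-subject synergy extraction on one synthetic recording.

Runs the preprocessing chain (segment -> 5 Hz zero-phase Butterworth ->
1000-frame time normalization -> pool -> z-score) and the correlation-matrix
PCA with Kaiser retention and varimax rotation, then prints the retained
components.
"""

import numpy as np

import synkin

gt = synkin.make_ground_truth(K=3, seed=1)
recs, _ = synkin.simulate_cohort(gt, n_subjects=1, n_grasps=10, n_repetitions=4, seed=1)

sm = synkin.preprocess_recording(recs[0])
print(f"pooled standardized matrix: {sm.data.shape[0]} frames x {sm.data.shape[1]} joints")

pcs = synkin.extract_pcs(sm)
print(f"retained components (eigenvalue > 1): k = {pcs.k}")
print("eigenvalues:", np.round(pcs.eigenvalues, 2))
print(f"variance explained: {100 * pcs.variance_explained:.1f}%")
for i, row in enumerate(pcs.loadings):
    top = np.argsort(-np.abs(row))[:3]
    desc = ", ".join(f"{synkin.JOINT_NAMES[j]}={row[j]:+.2f}" for j in top)
    print(f"  PC{i}: strongest joints -> {desc}")

# Each retained loading vector is one kinematic synergy candidate of this
# subject: the joints listed move together (same sign) or in opposition
# (opposite sign); the variance explained is the retained eigenvalue mass
# over the 17 standardized joints.
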