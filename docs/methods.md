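# Methods

## The analysis model

`synkin` treats each subject's grasping data as realizations of a
low-dimensional linear model in standardized joint space: after per-joint
z-scoring, a movement frame x(t) ∈ R¹⁷ is assumed to be approximately
Σ_k a_k(t) w_k + ε(t), with a small number of fixed loading vectors w_k
(synergies) and uncorrelated residual noise. Three consequences shape the
pipeline:

- PCA is run on the **correlation matrix** (equivalently, on z-scored
  data). Joints differ widely in range of motion (a PIP flexes ~100°, the
  inter-finger abductions move a few degrees); covariance-based PCA would
  let large-range joints dominate, while standardization weighs all joints
  equally. The result is invariant to positive per-column rescaling of the
  input (tested).
- **Kaiser retention** (eigenvalue strictly > 1) keeps components that
  explain more than one standardized joint's worth of variance. Ties at
  exactly 1 are excluded; an input with exactly identity correlation
  retains nothing and is reported as a degenerate-retention error rather
  than silently returning zero components.
- **Varimax rotation** with Kaiser row-normalization is applied to the
  retained loadings (eigenvectors × √eigenvalue). Rotation does not change
  the retained subspace or its total variance, so "variance explained"
  (Σ retained eigenvalues / 17) is computed from the pre-rotation
  eigenvalues. Rotated loading vectors are reported with unit Euclidean
  norm and a deterministic sign (largest-magnitude entry positive): the
  sign of a loading vector is not identified — the clustering distance
  uses |cos| — so a convention is needed only for reproducibility.

The implementation of varimax is the classical pairwise planar-rotation
sweep: for each factor pair the criterion (sum over factors of the variance
of squared loadings) has a closed-form optimal angle; sweeps continue until
the criterion gains < 1e-8 or 500 sweeps. Kaiser normalization scales each
variable's loading row to unit communality during optimization and restores
it afterwards. The rotation is checked in tests against a 0.1°-grid brute
force (2-factor problems) and against an independent library
implementation on the shared objective.

Cohort aggregation pools every subject's rotated loading vectors and
clusters them with complete linkage on the line angle
arccos(|cosine|) ∈ [0°, 90°] (the cosine argument is clamped to [0, 1]
before arccos so floating-point rounding cannot leave the domain). The cut
is chosen at the largest gap between consecutive merge heights — the point
where continuing to merge would join markedly less similar groups —
with the earliest gap winning ties; the cut height is reported as the
midpoint of the gap, and callers can override it with an explicit cut in
degrees. When every merge happens at the same height there is no gap and
the cut is refused rather than guessed. Cluster "variance" is defined by
count (PCs in the cluster / pooled total), so fractions sum to exactly 1;
the synergy set is the smallest descending-fraction prefix reaching the
80% threshold. Before averaging a cluster's members, each vector is
sign-aligned to the member with the greatest total |dot| to all others;
prevalence counts distinct subjects (one subject may contribute two PCs to
one cluster, so the PC count is reported separately).

## Preprocessing choices

Pipeline order is fixed: segment by labels → filter → time-normalize →
pool → standardize.

- Filtering is zero-phase (forward–backward 2nd-order Butterworth, 5 Hz),
  giving an effective amplitude gain 1/(1+(f/f_c)⁴); edges use reflective
  padding of 3 × filter order samples, and segments too short for the
  padding are an error, never silently truncated. Filtering is applied per
  movement segment by default; `filter_whole_stream=True` filters the
  continuous recording first instead (the two differ only near segment
  edges — the choice is exposed because either order is defensible).
- Time normalization linearly interpolates each repetition onto 1000
  equispaced points over the closed interval [first frame, last frame], so
  onset and offset postures are preserved exactly and repetitions of
  different durations become comparable.
- Standardization uses the population SD (ddof = 0) of the pooled
  **movement** frames only; rest frames never enter the statistics. A
  zero-variance joint makes correlation undefined and raises an error
  naming the joint. Across subjects, the mean variance explained is
  reported with the sample SD (ddof = 1), the usual convention for a
  between-subject dispersion.
- Oversampling (for multi-device streams recorded at different rates) is
  linear interpolation on a uniform grid spanning the original first and
  last instants; labels are carried by the nearest *preceding* original
  sample so a movement can never be labeled before its recorded onset.
  Downsampling is refused.

## The synthetic cohort generator

The generator emulates a glove-based grasp protocol: per subject,
`n_grasps` × `n_repetitions` movements of 5 s separated by 3 s rest, exact
stimulus/repetition labels, at a nominal 50 Hz (an ample 10× the 5 Hz
analysis bandwidth; real acquisitions at higher rates are handled by the
same pipeline unchanged). Defaults follow the protocol the package targets:
20 grasps, 6 repetitions, cohorts up to 77 subjects.

Planted structure. Ground truth is a set of K unit-norm loading vectors:
two broad *base* modules on complementary joint groups that together cover
all 17 joints, plus sparse *refinement* contrasts confined to 2–3 joints
inside one base support and constructed orthogonal to every other module
(exactly orthogonal at `overlap = 0`; `overlap > 0` blends in a shared
dense component). Two modelling facts motivate this shape rather than
arbitrary dense orthogonal vectors. First, real synergies recruit subsets
of joints, and near-simple structure is what an orthogonal rotation toward
simple structure can recover — recovery of a planted basis is only a
meaningful benchmark if the basis is identifiable by the method. Second,
every joint of a real hand moves during grasping; if a subject's expressed
modules left some joints motionless, those joints would carry pure sensor
noise, and the top sample eigenvalue of a standardized pure-noise block
always drifts above 1, corrupting Kaiser retention (and at zero noise the
joints would have zero variance outright). The two base modules are
therefore expressed by every subject, and prevalence applies to the
refinements.

Activations. During a movement, each recruited module follows a
raised-cosine bump with random amplitude (8–25°), random center
(25–75% of the movement) and random width, zero at onset and offset —
mimicking reach–grasp–release. An expressed module is recruited in each
repetition with probability 0.75 (`participation`): not every synergy
serves every grasp, and the per-repetition variation also decorrelates
module activations across the pooled frames, without which all bump-shaped
activations would share enough common time course to bias the per-subject
rotation. `activation_smoothness` (default 0.5) sets the lower bound of
the bump's half-width fraction. Channel noise is i.i.d. Gaussian, scaled
per channel by a random range-of-motion factor (20–60°), added to movement
and rest alike; postures are uniform in 10–40°.

Coordinate frames. Planted loadings are defined in degree space; the
analysis recovers directions in the **standardized** frame, i.e. the
planted vector with each component divided by that joint's SD
(renormalized). `standardized_ground_truth` maps planted vectors through
the per-subject scales the pipeline itself computed; all recovery
comparisons use it. Comparing degree-space vectors directly would conflate
rescaling with genuine misestimation.

What the generator does not emulate: biomechanical coupling constraints,
object contact, drift or sensor calibration error, inter-repetition
learning effects, or non-orthogonal/correlated true synergies (except via
`overlap`). Passing recovery tests therefore shows the estimator is
correct under its own model assumptions at realistic noise, not that real
hands satisfy those assumptions.

## Problem sizes and determinism

Tests run on small cohorts (1–5 subjects, 6–10 grasps, 25 Hz); the
standard validation study in `scripts/acceptance.py` and the end-to-end
recovery test use 20 subjects × 20 grasps × 6 repetitions with 4 planted
modules (prevalence 1, 1, 0.6, 0.4; noise SD 0.1), a scale at which the
whole analysis runs in seconds. All randomness flows from a single
`numpy` Generator seed: same seed, same cohort, same catalog, byte-identical
report tables.

## Known limitations

- The largest-gap cut rule is a heuristic; with a pool whose angles vary
  smoothly it can be unstable, which is why an explicit `cut` override
  exists (both behaviours are first-class).
- Kaiser retention is known to over-retain when effective sample size is
  small; heavily low-pass-filtered data contain far fewer independent
  frames than rows.
- Loading-vector averaging after sign alignment is not a true Fréchet mean
  on the projective space; for tight clusters (the intended regime) the
  difference is negligible.
- Left- and right-hand recordings are passed through unchanged (no
  mirroring is applied).
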