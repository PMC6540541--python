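"""Synthetic multi-subject cohorts with planted, known synergy structure.

The generator emulates a data-glove grasp protocol: each subject repeats
each of ``n_grasps`` grasps ``n_repetitions`` times; a repetition is ~5 s of
movement separated by ~3 s of rest. During movement, the 17 joint angles are
driven by a small set of latent modules — fixed unit-norm loading vectors
shared across the cohort — mixed with smooth, nonnegative activations that
vanish at movement onset and offset (raised-cosine bumps with a random
amplitude, center and width per repetition, mimicking reach–grasp–release).
Which modules a subject expresses is drawn per subject from the modules'
prevalence probabilities, so cluster-level prevalence counts have a ground
truth.

Planted loading vectors mimic how kinematic synergies are organized: two
broad "base" modules with complementary joint supports that together cover
all 17 joints (the universal reach-and-close components every grasp
recruits), plus sparse refinement modules, each a contrast confined to a
few joints inside one base support and orthogonal to it. At ``overlap=0``
all modules are exactly orthogonal by construction; ``overlap > 0`` blends
a shared dense component into every module. Because the base modules are
expressed by every subject, every joint carries movement variance in every
recording — as in real hands, where no joint is ever completely still
during grasping — which keeps per-joint standardization and
eigenvalue-based component retention well defined.

The signal model for a movement frame is

    angles(t) = posture + sum_k a_k(t) * loading_k + range * noise(t)

with the activations ``a_k`` carrying the degree scale, per-channel ranges
scaling i.i.d. Gaussian noise, and rest frames sitting at the (noisy)
posture baseline. With ``noise_sd = 0`` the centered movement frames lie
exactly in the span of the expressed loadings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .schema import N_JOINTS, JointAngleRecording

__all__ = [
    "GroundTruthSynergies",
    "CohortManifest",
    "make_ground_truth",
    "simulate_cohort",
    "standardized_ground_truth",
]


@dataclass
class GroundTruthSynergies:
    """Planted latent structure of a synthetic cohort.

    Attributes
    ----------
    loadings
        ``K x 17`` matrix of unit-norm planted loading vectors.
    prevalence
        Per-module probability that a subject expresses the module.
    activation_smoothness
        In ``(0, 1]``: lower bound of the activation bump half-width as a
        fraction of its maximal extent; larger values give wider, smoother
        bumps.
    noise_sd
        Additive channel noise SD in standardized units (scaled by each
        channel's range when converting to degrees).
    """

    loadings: np.ndarray
    prevalence: np.ndarray
    activation_smoothness: float = 0.5
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        K = self.loadings.shape[0]
        if self.loadings.ndim != 2 or self.loadings.shape[1] != N_JOINTS:
            raise ParameterError(
                f"loadings must be K x {N_JOINTS}, got {self.loadings.shape}"
            )
        norms = np.linalg.norm(self.loadings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ParameterError("each planted loading must have unit norm")
        if self.prevalence.shape != (K,):
            raise ParameterError("prevalence must have one entry per module")
        if ((self.prevalence < 0) | (self.prevalence > 1)).any():
            raise ParameterError("prevalence entries must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 < self.activation_smoothness <= 1:
            raise ParameterError("activation_smoothness must be in (0, 1]")

    @property
    def n_modules(self) -> int:
        return self.loadings.shape[0]


@dataclass
class CohortManifest:
    """Reproducibility record of a simulated cohort: same seed, same cohort."""

    seed: int
    n_subjects: int
    n_grasps: int
    n_repetitions: int
    sample_rate: float
    subject_ids: list[str] = field(default_factory=list)
    expressed_modules: list[list[int]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortManifest":
        return cls(**json.loads(Path(path).read_text()))


def make_ground_truth(
    K: int,
    overlap: float = 0.0,
    seed: int | np.random.Generator = 0,
    prevalence: np.ndarray | None = None,
    activation_smoothness: float = 0.5,
    noise_sd: float = 0.1,
) -> GroundTruthSynergies:
    """Draw ``K`` planted unit-norm loading vectors.

    Modules 0 and 1 are broad base modules on complementary joint groups
    covering all 17 joints (for ``K = 1`` a single dense module); modules
    2.. are refinement contrasts, each confined to a few joints inside one
    base support and constructed orthogonal to every previously placed
    module. ``overlap = 0`` therefore gives pairwise cosine exactly 0.
    With ``overlap > 0`` a shared dense unit vector ``s`` is blended in:
    ``l_k <- normalize(sqrt(1-overlap) l_k + sqrt(overlap) s)``.

    Raises
    ------
    ParameterError
        If ``K`` is outside ``1..17`` or ``overlap`` outside ``[0, 1]``.
    """
    if not 1 <= K <= N_JOINTS:
        raise ParameterError(f"K must be in 1..{N_JOINTS}, got {K}")
    if not 0 <= overlap <= 1:
        raise ParameterError(f"overlap must be in [0, 1], got {overlap}")
    rng = np.random.default_rng(seed)
    loadings = _planted_loadings(K, rng)

    if overlap > 0:
        shared = rng.standard_normal(N_JOINTS)
        shared /= np.linalg.norm(shared)
        loadings = np.sqrt(1 - overlap) * loadings + np.sqrt(overlap) * shared
        loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)

    if prevalence is None:
        prevalence = np.ones(K)
    return GroundTruthSynergies(
        loadings=loadings,
        prevalence=prevalence,
        activation_smoothness=activation_smoothness,
        noise_sd=noise_sd,
    )


def _random_weights(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.5, 1.0, size=size) * rng.choice([-1.0, 1.0], size=size)


def _planted_loadings(K: int, rng: np.random.Generator) -> np.ndarray:
    """Base modules on complementary blocks + nested orthogonal contrasts."""
    perm = rng.permutation(N_JOINTS)
    loadings = np.zeros((K, N_JOINTS))
    if K == 1:
        w = _random_weights(rng, N_JOINTS)
        loadings[0] = w / np.linalg.norm(w)
        return loadings

    half = N_JOINTS // 2
    blocks = [perm[:half], perm[half:]]
    for b in (0, 1):
        w = _random_weights(rng, len(blocks[b]))
        loadings[b, blocks[b]] = w / np.linalg.norm(w)

    # refinement contrasts: small disjoint supports inside a base block,
    # orthogonalized against everything already living on those joints.
    # a block of size m hosts at most m - 1 contrasts beyond its base.
    unused = [list(blocks[0]), list(blocks[1])]
    used = [1, 1]  # vectors living on each block so far (the base)
    for k in range(2, K):
        b = (k - 2) % 2
        if used[b] >= len(blocks[b]):
            b = 1 - b
        if len(unused[b]) < 2 <= len(unused[1 - b]) and used[1 - b] < len(blocks[1 - b]):
            b = 1 - b
        used[b] += 1
        if len(unused[b]) >= 2:
            take = 3 if len(unused[b]) >= 3 else 2
            support = np.array([unused[b].pop() for _ in range(take)])
        else:  # blocks exhausted: dense contrast over a whole base block
            support = blocks[b]
        w = _random_weights(rng, len(support))
        prior = loadings[:k, support]  # rows with mass on these joints
        prior = prior[np.linalg.norm(prior, axis=1) > 0]
        if prior.size:
            # project w onto the orthogonal complement of the prior rows
            gram = prior @ prior.T
            coef = np.linalg.solve(gram, prior @ w)
            w = w - prior.T @ coef
        norm = np.linalg.norm(w)
        if norm < 1e-9:  # random draw fell in the span; redraw deterministically
            w = rng.standard_normal(len(support))
            w -= prior.T @ np.linalg.solve(prior @ prior.T, prior @ w)
            norm = np.linalg.norm(w)
        loadings[k, support] = w / norm
    return loadings


def _raised_cosine_bump(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """cos^2 bump on |u - center| < width, zero outside (and at endpoints)."""
    out = np.zeros_like(u)
    mask = np.abs(u - center) < width
    out[mask] = np.cos(np.pi * (u[mask] - center) / (2 * width)) ** 2
    return out


def simulate_cohort(
    gt: GroundTruthSynergies,
    n_subjects: int = 77,
    n_grasps: int = 20,
    n_repetitions: int = 6,
    sample_rate: float = 50.0,
    movement_s: float = 5.0,
    rest_s: float = 3.0,
    participation: float = 0.75,
    seed: int | np.random.Generator = 0,
) -> tuple[list[JointAngleRecording], CohortManifest]:
    """Simulate a labeled cohort of joint-angle recordings.

    Each subject expresses module ``k`` with probability
    ``gt.prevalence[k]``, except that the two base modules (0 and 1, which
    jointly cover all 17 joints) are always expressed — every joint of a
    real hand moves during grasping, and motionless joints would make
    per-joint standardization degenerate. At least two modules are always
    present (all of them if fewer exist). An expressed module is recruited
    in each repetition with probability ``participation`` (not every
    synergy serves every grasp), which also decorrelates the module
    activations across the pooled frames. Labels are exact: stimulus ``g``
    and repetition ``r`` on movement frames, zeros at rest, one leading
    rest block and one after every movement.

    Returns the list of recordings and a :class:`CohortManifest` recording
    which modules each subject expresses.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    if not 0 < participation <= 1:
        raise ParameterError("participation must be in (0, 1]")
    n_mov = int(round(movement_s * sample_rate))
    n_rest = int(round(rest_s * sample_rate))
    if n_mov < 2:
        raise ParameterError("movement duration must span at least 2 frames")
    rng = np.random.default_rng(seed)
    K = gt.n_modules
    smooth = gt.activation_smoothness

    width = len(str(n_subjects))
    recordings: list[JointAngleRecording] = []
    manifest = CohortManifest(
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
        n_subjects=n_subjects,
        n_grasps=n_grasps,
        n_repetitions=n_repetitions,
        sample_rate=sample_rate,
    )

    u = np.linspace(0.0, 1.0, n_mov)
    for s in range(n_subjects):
        sid = f"S{s + 1:0{width}d}"
        expressed = np.flatnonzero(rng.random(K) < gt.prevalence)
        base = np.arange(min(2, K))  # base modules are always on
        expressed = np.union1d(expressed, base)

        posture = rng.uniform(10.0, 40.0, size=N_JOINTS)
        chan_range = rng.uniform(20.0, 60.0, size=N_JOINTS)

        blocks: list[np.ndarray] = []
        stim: list[np.ndarray] = []
        rep: list[np.ndarray] = []

        def rest_block() -> None:
            blocks.append(np.tile(posture, (n_rest, 1)))
            stim.append(np.zeros(n_rest, dtype=int))
            rep.append(np.zeros(n_rest, dtype=int))

        rest_block()
        for g in range(1, n_grasps + 1):
            for r in range(1, n_repetitions + 1):
                frames = np.tile(posture, (n_mov, 1))
                for k in expressed:
                    if rng.random() > participation:
                        continue
                    amp = rng.uniform(8.0, 25.0)
                    center = rng.uniform(0.25, 0.75)
                    half = min(center, 1.0 - center)
                    w = half * rng.uniform(smooth, 1.0)
                    a = amp * _raised_cosine_bump(u, center, w)
                    frames += np.outer(a, gt.loadings[k])
                blocks.append(frames)
                stim.append(np.full(n_mov, g, dtype=int))
                rep.append(np.full(n_mov, r, dtype=int))
                rest_block()

        angles = np.concatenate(blocks)
        if gt.noise_sd > 0:
            angles = angles + gt.noise_sd * chan_range * rng.standard_normal(
                angles.shape
            )
        recordings.append(
            JointAngleRecording(
                subject_id=sid,
                sample_rate=sample_rate,
                angles=angles,
                stimulus=np.concatenate(stim),
                repetition=np.concatenate(rep),
            )
        )
        manifest.subject_ids.append(sid)
        manifest.expressed_modules.append([int(k) for k in expressed])

    return recordings, manifest


def standardized_ground_truth(
    gt: GroundTruthSynergies, scales: np.ndarray
) -> np.ndarray:
    """Planted loading vectors expressed in the analysis' standardized frame.

    The pipeline z-scores each joint before PCA, so a module planted with
    degree-space loading ``l_k`` is recovered as ``normalize(l_k / s)``
    where ``s`` holds the joints' (pooled movement) standard deviations.
    ``scales`` is one 17-vector of channel SDs, or a ``n_subjects x 17``
    stack (one per subject, e.g. from the pipeline's own
    :class:`~synkin.preprocessing.SubjectMatrix` scales), in which case the
    per-subject frames are averaged before renormalizing. Returns a
    ``K x 17`` matrix of unit vectors — the correct comparison target for
    recovered loadings.
    """
    scales = np.atleast_2d(np.asarray(scales, dtype=float))
    if scales.shape[1] != N_JOINTS or (scales <= 0).any():
        raise ParameterError("scales must be positive 17-vectors")
    per_subj = gt.loadings[None, :, :] / scales[:, None, :]
    per_subj /= np.linalg.norm(per_subj, axis=2, keepdims=True)
    mean = per_subj.mean(axis=0)
    return mean / np.linalg.norm(mean, axis=1, keepdims=True)
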