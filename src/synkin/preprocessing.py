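"""From labeled recordings to the per-subject standardized matrix.

Pipeline order is fixed: (optional linear-interpolation oversampling) →
label-based segmentation into movement repetitions → zero-phase low-pass
Butterworth filtering per segment → linear time-normalization of each
repetition to a fixed frame count (1000 by default, covering reach, grasp
and release) → pooling of all repetitions of a subject into one matrix →
per-column z-scoring. Rest frames never enter the pooled matrix, so
standardization statistics come from movement frames only.

Standardizing gives every joint — including those with small range of
motion — equal weight in the subsequent correlation-matrix PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import DataError, ParameterError
from .schema import N_JOINTS, JointAngleRecording, JOINT_NAMES, iter_movement_blocks

__all__ = [
    "RepetitionSegment",
    "SubjectMatrix",
    "resample_streams",
    "segment_repetitions",
    "lowpass_filter",
    "rescale_to_frames",
    "pool_and_standardize",
    "preprocess_recording",
]

N_FRAMES_DEFAULT = 1000


@dataclass
class RepetitionSegment:
    """One grasp execution (reach + grasp + release) for one subject."""

    subject_id: str
    grasp_id: int
    repetition_id: int
    angles: np.ndarray  # frames x 17, degrees


@dataclass
class SubjectMatrix:
    """Pooled, standardized movement frames of one subject.

    ``data`` is ``(n_frames_per_segment * n_segments) x 17`` with column
    mean 0 and population SD 1; ``segment_index`` maps each row to the
    ordinal of its source segment in ``segments`` (``(grasp, repetition)``
    pairs). ``center``/``scale`` are the per-joint mean and SD (degrees)
    removed by standardization, kept so results can be mapped back to the
    degree frame.
    """

    subject_id: str
    data: np.ndarray
    segment_index: np.ndarray
    segments: list[tuple[int, int]]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None


def resample_streams(
    rec: JointAngleRecording, target_rate: float
) -> JointAngleRecording:
    """Oversample a recording to ``target_rate`` by linear interpolation.

    Angle channels are linearly interpolated on a uniform grid spanning the
    original first and last sample instants (both preserved exactly);
    labels are carried by the nearest *preceding* original sample, so
    movement onsets are never anticipated. Downsampling is refused.
    """
    if target_rate < rec.sample_rate:
        raise ParameterError(
            f"downsampling not supported: target {target_rate} Hz < "
            f"recording rate {rec.sample_rate} Hz"
        )
    if target_rate == rec.sample_rate or rec.n_frames < 2:
        return JointAngleRecording(
            rec.subject_id,
            target_rate,
            rec.angles.copy(),
            rec.stimulus.copy(),
            rec.repetition.copy(),
        )
    n = rec.n_frames
    duration = (n - 1) / rec.sample_rate
    m = int(round(duration * target_rate)) + 1
    t_old = np.arange(n) / rec.sample_rate
    t_new = np.linspace(0.0, duration, m)
    angles = np.empty((m, N_JOINTS))
    for j in range(N_JOINTS):
        angles[:, j] = np.interp(t_new, t_old, rec.angles[:, j])
    # nearest preceding sample; guard fp jitter by nudging query times up
    src = np.searchsorted(t_old, t_new * (1 + 1e-12) + 1e-15, side="right") - 1
    src = np.clip(src, 0, n - 1)
    return JointAngleRecording(
        rec.subject_id, target_rate, angles, rec.stimulus[src], rec.repetition[src]
    )


def segment_repetitions(rec: JointAngleRecording) -> list[RepetitionSegment]:
    """Split a recording into its labeled movement repetitions.

    Returns one variable-length segment per contiguous ``stimulus > 0``
    block, in temporal order; rest frames are dropped.
    """
    return [
        RepetitionSegment(rec.subject_id, g, r, rec.angles[start:stop].copy())
        for start, stop, g, r in iter_movement_blocks(rec.stimulus, rec.repetition)
    ]


def lowpass_filter(
    angles: np.ndarray,
    sample_rate: float,
    cutoff: float = 5.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase (forward–backward) low-pass Butterworth filtering.

    Applied per channel with reflective edge padding of length
    ``3 * order``; DC is preserved exactly. The two-way pass squares the
    magnitude response, so the effective amplitude gain at frequency f is
    ``1 / (1 + (f / cutoff)^(2*order))``.
    """
    angles = np.asarray(angles, dtype=float)
    if sample_rate <= 2 * cutoff:
        raise ParameterError(
            f"sample_rate must exceed 2 x cutoff ({2 * cutoff} Hz), got {sample_rate}"
        )
    padlen = 3 * order
    if angles.shape[0] <= padlen:
        raise DataError(
            f"segment of {angles.shape[0]} frames is too short for stable "
            f"two-way filtering (needs > {padlen})"
        )
    b, a = butter(order, cutoff, btype="low", fs=sample_rate)
    return filtfilt(b, a, angles, axis=0, padtype="even", padlen=padlen)


def rescale_to_frames(
    segment: RepetitionSegment | np.ndarray, n: int = N_FRAMES_DEFAULT
) -> RepetitionSegment | np.ndarray:
    """Time-normalize a repetition to exactly ``n`` frames.

    Each channel is linearly interpolated onto ``n`` equispaced points over
    the closed interval [first frame, last frame]; both endpoint postures
    are preserved exactly.
    """
    arr = segment.angles if isinstance(segment, RepetitionSegment) else segment
    arr = np.asarray(arr, dtype=float)
    m = arr.shape[0]
    if m < 2:
        raise DataError("cannot rescale a segment with fewer than 2 frames")
    if n < 2:
        raise ParameterError("target frame count must be >= 2")
    pos = np.linspace(0.0, m - 1.0, n)
    i0 = np.minimum(pos.astype(int), m - 2)
    frac = (pos - i0)[:, None]
    out = arr[i0] * (1.0 - frac) + arr[i0 + 1] * frac
    out[0], out[-1] = arr[0], arr[-1]
    if isinstance(segment, RepetitionSegment):
        return RepetitionSegment(
            segment.subject_id, segment.grasp_id, segment.repetition_id, out
        )
    return out


def pool_and_standardize(segments: list[RepetitionSegment]) -> SubjectMatrix:
    """Concatenate a subject's repetitions and z-score each joint column.

    Standardization uses the pooled per-column mean and population SD
    (ddof=0); a zero-variance column is an error because the joint would be
    undefined in correlation space.
    """
    if len(segments) < 2:
        raise ParameterError("need at least 2 segments to pool")
    subject_ids = {s.subject_id for s in segments}
    if len(subject_ids) != 1:
        raise ParameterError(f"segments mix subjects: {sorted(subject_ids)}")
    data = np.concatenate([s.angles for s in segments])
    if not np.isfinite(data).all():
        raise DataError("non-finite values in pooled segments")
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd < 1e-12)
    if dead.size:
        names = ", ".join(JOINT_NAMES[j] for j in dead)
        raise DataError(f"zero-variance joint column(s): {names}")
    seg_index = np.concatenate(
        [np.full(s.angles.shape[0], i, dtype=int) for i, s in enumerate(segments)]
    )
    return SubjectMatrix(
        subject_id=segments[0].subject_id,
        data=(data - mean) / sd,
        segment_index=seg_index,
        segments=[(s.grasp_id, s.repetition_id) for s in segments],
        center=mean,
        scale=sd,
    )


def preprocess_recording(
    rec: JointAngleRecording,
    cutoff: float = 5.0,
    order: int = 2,
    n_frames: int = N_FRAMES_DEFAULT,
    filter_whole_stream: bool = False,
) -> SubjectMatrix:
    """Run the full preprocessing chain for one subject.

    ``filter_whole_stream=True`` filters the continuous recording before
    segmentation instead of filtering each repetition separately (the
    default); results differ only near segment edges.
    """
    if filter_whole_stream:
        filtered = lowpass_filter(rec.angles, rec.sample_rate, cutoff, order)
        rec = JointAngleRecording(
            rec.subject_id, rec.sample_rate, filtered, rec.stimulus, rec.repetition
        )
        segments = segment_repetitions(rec)
    else:
        segments = segment_repetitions(rec)
        for seg in segments:
            seg.angles = lowpass_filter(seg.angles, rec.sample_rate, cutoff, order)
    segments = [rescale_to_frames(seg, n_frames) for seg in segments]
    return pool_and_standardize(segments)
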