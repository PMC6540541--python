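"""The 17-joint coordinate frame and the labeled recording container.

Every stage of the pipeline — simulation, preprocessing, PCA, clustering —
expresses hand posture in the same ordered set of 17 calibrated anatomical
angles (degrees). The order of :data:`JOINT_NAMES` is the column order of
every matrix in the package; loading vectors are only comparable because all
subjects share this frame.

Nomenclature: digits are numbered 1 (thumb) to 5 (little finger); ``_F``
denotes flexion/extension, ``_A`` abduction/deviation. ``CMC5_F`` is palmar
arching (cupping of the palm); ``MCP3-4_A`` / ``MCP4-5_A`` are the relative
abductions between adjacent finger MCPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError, StructureError

__all__ = [
    "JOINT_NAMES",
    "SIGN_CONVENTIONS",
    "N_JOINTS",
    "JointSchema",
    "JointAngleRecording",
]

JOINT_NAMES: tuple[str, ...] = (
    "CMC1_F",
    "CMC1_A",
    "MCP1_F",
    "IP1_F",
    "MCP2_F",
    "PIP2_F",
    "MCP3_F",
    "PIP3_F",
    "MCP4_F",
    "PIP4_F",
    "MCP5_F",
    "PIP5_F",
    "MCP3-4_A",
    "MCP4-5_A",
    "CMC5_F",
    "WRIST_F",
    "WRIST_A",
)

N_JOINTS = len(JOINT_NAMES)

#: Allowed positive-direction categories for an angle.
SIGN_CATEGORIES = frozenset(
    {"flexion+", "abduction+", "radial-deviation+", "fingers-separated+"}
)

#: Positive direction of each angle: flexion for all ``_F`` angles,
#: abduction for the thumb CMC, radial deviation for the wrist, and
#: fingers-separated for the inter-finger abductions.
SIGN_CONVENTIONS: dict[str, str] = {
    name: (
        "radial-deviation+"
        if name == "WRIST_A"
        else "fingers-separated+"
        if name in ("MCP3-4_A", "MCP4-5_A")
        else "abduction+"
        if name == "CMC1_A"
        else "flexion+"
    )
    for name in JOINT_NAMES
}


@dataclass(frozen=True)
class JointSchema:
    """Ordered list of the 17 anatomical angles with sign conventions."""

    names: tuple[str, ...] = JOINT_NAMES
    sign_convention: dict[str, str] = field(
        default_factory=lambda: dict(SIGN_CONVENTIONS)
    )

    def __post_init__(self) -> None:
        if len(self.names) != N_JOINTS:
            raise SchemaError(
                f"schema must have exactly {N_JOINTS} angles, got {len(self.names)}"
            )
        if len(set(self.names)) != len(self.names):
            raise SchemaError("angle names must be unique")
        for name in self.names:
            conv = self.sign_convention.get(name)
            if conv not in SIGN_CATEGORIES:
                raise SchemaError(
                    f"angle {name!r} has invalid sign convention {conv!r}"
                )

    def index(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_SCHEMA = JointSchema()


@dataclass
class JointAngleRecording:
    """Labeled multi-channel joint-angle time series for one subject.

    Parameters
    ----------
    subject_id
        Identifier of the subject.
    sample_rate
        Sampling frequency in Hz.
    angles
        ``frames x 17`` matrix of calibrated anatomical angles in degrees,
        columns ordered as :data:`JOINT_NAMES`.
    stimulus
        Per-frame grasp label; ``0`` marks rest, ``g >= 1`` a grasp id.
    repetition
        Per-frame repetition counter within a grasp; ``0`` at rest.
    """

    subject_id: str
    sample_rate: float
    angles: np.ndarray
    stimulus: np.ndarray
    repetition: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.stimulus = np.asarray(self.stimulus, dtype=int)
        self.repetition = np.asarray(self.repetition, dtype=int)
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise SchemaError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.angles.ndim != 2 or self.angles.shape[1] != N_JOINTS:
            raise SchemaError(
                f"angles must be frames x {N_JOINTS}, got shape {self.angles.shape}"
            )
        n = self.angles.shape[0]
        if self.stimulus.shape != (n,) or self.repetition.shape != (n,):
            raise SchemaError(
                "stimulus and repetition must have one entry per frame "
                f"({n}), got {self.stimulus.shape} and {self.repetition.shape}"
            )
        rest_mismatch = (self.stimulus == 0) != (self.repetition == 0)
        if rest_mismatch.any():
            idx = int(np.flatnonzero(rest_mismatch)[0])
            raise StructureError(
                f"frame {idx}: stimulus and repetition disagree on rest "
                f"(stimulus={self.stimulus[idx]}, repetition={self.repetition[idx]})"
            )
        self._check_contiguous_blocks()

    def _check_contiguous_blocks(self) -> None:
        # each (grasp, repetition) pair must label exactly one contiguous run
        seen: set[tuple[int, int]] = set()
        for start, stop, g, r in iter_movement_blocks(self.stimulus, self.repetition):
            if (g, r) in seen:
                raise StructureError(
                    f"repetition block (grasp={g}, rep={r}) is non-contiguous: "
                    f"reappears at frame {start}"
                )
            seen.add((g, r))


def iter_movement_blocks(stimulus: np.ndarray, repetition: np.ndarray):
    """Yield ``(start, stop, grasp, repetition)`` for each contiguous
    movement run (half-open frame interval), in temporal order."""
    n = len(stimulus)
    if n == 0:
        return
    key = np.stack([stimulus, repetition])
    change = np.flatnonzero((np.diff(key, axis=1) != 0).any(axis=0)) + 1
    bounds = np.concatenate([[0], change, [n]])
    for start, stop in zip(bounds[:-1], bounds[1:]):
        g = int(stimulus[start])
        if g > 0:
            yield int(start), int(stop), g, int(repetition[start])
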