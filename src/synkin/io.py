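"""Reading and writing labeled joint-angle recordings.

The canonical on-disk format is a delimited long table, one row per frame:

    subject_id, frame, stimulus, repetition, CMC1_F, ..., WRIST_A

with a leading ``# sample_rate_hz=<value>`` comment line (the column set
itself carries no rate). ``.tsv`` files are tab-separated, anything else
comma-separated. A second layout, ``matrix``, is the same table without the
``subject_id``/``frame`` columns (the subject id is taken from the file name
or passed explicitly). An optional adapter ingests NinaPro-style MAT files
that already contain the 17 calibrated angles; raw 22-sensor glove values
are rejected because sensor calibration is out of scope here.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .schema import JOINT_NAMES, JointAngleRecording

__all__ = ["load_recording", "write_recording", "LABEL_COLUMNS"]

LABEL_COLUMNS = ("subject_id", "frame", "stimulus", "repetition")
_RATE_RE = re.compile(r"#\s*sample_rate_hz\s*=\s*([0-9.eE+-]+)")


def _sep_for(path: os.PathLike | str) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_rate_comment(path: Path) -> float | None:
    with open(path) as fh:
        first = fh.readline()
    m = _RATE_RE.match(first)
    return float(m.group(1)) if m else None


def load_recording(
    path: os.PathLike | str,
    layout: str = "long",
    sample_rate: float | None = None,
    subject_id: str | None = None,
) -> JointAngleRecording:
    """Load a labeled recording from disk.

    Parameters
    ----------
    path
        Input file.
    layout
        ``"long"`` (canonical long table), ``"matrix"`` (labels + angle
        columns only) or ``"ninapro-mat"`` (MAT file with calibrated
        ``angles``; requires scipy).
    sample_rate
        Sampling rate in Hz; overrides the file's ``# sample_rate_hz``
        comment. Required if the file carries none.
    subject_id
        Overrides the subject id stored in (or inferred from) the file.

    Raises
    ------
    SchemaError
        If an angle column is missing, duplicated, or unknown columns are
        present.
    StructureError
        If a (grasp, repetition) block is non-contiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "ninapro-mat":
        return _load_ninapro_mat(path, sample_rate, subject_id)
    if layout not in ("long", "matrix"):
        raise ParameterError(f"unknown layout {layout!r}")

    rate = sample_rate if sample_rate is not None else _read_rate_comment(path)
    if rate is None:
        raise ParameterError(
            f"{path}: no '# sample_rate_hz=' comment found; pass sample_rate="
        )
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")

    expected = set(JOINT_NAMES) | {"stimulus", "repetition"}
    if layout == "long":
        expected |= {"subject_id", "frame"}
    missing = [c for c in JOINT_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing angle column(s): {', '.join(missing)}")
    for lab in ("stimulus", "repetition"):
        if lab not in df.columns:
            raise SchemaError(f"{path}: missing label column {lab!r}")
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s): {', '.join(unknown)}")

    if subject_id is None:
        if layout == "long" and len(df):
            ids = df["subject_id"].astype(str).unique()
            if len(ids) != 1:
                raise SchemaError(
                    f"{path}: expected a single subject per file, found {list(ids)}"
                )
            subject_id = str(ids[0])
        else:
            subject_id = path.stem

    return JointAngleRecording(
        subject_id=subject_id,
        sample_rate=float(rate),
        angles=df[list(JOINT_NAMES)].to_numpy(dtype=float),
        stimulus=df["stimulus"].to_numpy(dtype=int),
        repetition=df["repetition"].to_numpy(dtype=int),
    )


def write_recording(rec: JointAngleRecording, path: os.PathLike | str) -> None:
    """Write a recording as a canonical long table (lossless to <1e-9)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": rec.subject_id,
            "frame": np.arange(rec.n_frames, dtype=int),
            "stimulus": rec.stimulus,
            "repetition": rec.repetition,
        }
    )
    for j, name in enumerate(JOINT_NAMES):
        df[name] = rec.angles[:, j] if rec.n_frames else np.empty(0)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={rec.sample_rate!r}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False, float_format="%.12g")


def _load_ninapro_mat(
    path: Path, sample_rate: float | None, subject_id: str | None
) -> JointAngleRecording:
    from scipy.io import loadmat

    mat = loadmat(path, squeeze_me=False)
    if "angles" not in mat:
        raise SchemaError(
            f"{path}: MAT file has no 'angles' field with calibrated angles"
        )
    angles = np.asarray(mat["angles"], dtype=float)
    if angles.ndim != 2 or angles.shape[1] != len(JOINT_NAMES):
        raise SchemaError(
            f"{path}: expected frames x 17 calibrated angles, got shape "
            f"{angles.shape} — raw glove sensor matrices are not accepted"
        )

    def _field(*names: str) -> np.ndarray:
        for nm in names:  # relabeled fields take precedence when present
            if nm in mat:
                return np.asarray(mat[nm]).reshape(-1)
        raise SchemaError(f"{path}: none of the fields {names} present")

    stimulus = _field("restimulus", "stimulus")
    repetition = _field("rerepetition", "repetition")
    if sample_rate is None:
        if "frequency" in mat:
            sample_rate = float(np.asarray(mat["frequency"]).reshape(-1)[0])
        else:
            raise ParameterError(f"{path}: pass sample_rate= (no 'frequency' field)")
    if subject_id is None:
        if "subject" in mat:
            subject_id = str(int(np.asarray(mat["subject"]).reshape(-1)[0]))
        else:
            subject_id = path.stem
    return JointAngleRecording(
        subject_id=subject_id,
        sample_rate=float(sample_rate),
        angles=angles,
        stimulus=stimulus,
        repetition=repetition,
    )
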