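"""Per-subject synergy extraction: correlation-matrix PCA with Kaiser
retention and varimax rotation.

For each subject the 17x17 correlation matrix of the pooled standardized
frames is eigendecomposed; components with eigenvalue strictly greater
than 1 are retained (Kaiser criterion: a component must explain more than a
single standardized joint). The retained loadings (eigenvectors scaled by
the square root of their eigenvalues) are then rotated by varimax with
Kaiser row-normalization, which seeks "simple structure" — each joint
loading strongly on few components — and each rotated loading vector is
rescaled to unit Euclidean norm with a deterministic sign (largest-|entry|
positive). Variance explained is the retained eigenvalue mass over 17 and
is invariant to the rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateRetentionError, ParameterError
from .preprocessing import SubjectMatrix
from .schema import N_JOINTS, JOINT_NAMES

__all__ = [
    "PCSet",
    "extract_pcs",
    "varimax_rotate",
    "varimax_criterion",
    "CohortSummary",
    "cohort_summary",
]


@dataclass
class PCSet:
    """Retained, rotated principal components of one subject.

    ``loadings`` is ``k x 17`` (rows are unit-norm rotated loading
    vectors); ``eigenvalues`` are the retained pre-rotation
    correlation-matrix eigenvalues, descending; ``variance_explained`` is
    their sum over 17.
    """

    subject_id: str
    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: float

    @property
    def k(self) -> int:
        return self.loadings.shape[0]


def varimax_criterion(loadings: np.ndarray, normalize: bool = True) -> float:
    """Varimax objective: sum over factors of the variance of squared
    loadings (computed on the Kaiser row-normalized matrix if
    ``normalize``). ``loadings`` is ``k x p`` with factors as rows."""
    A = np.asarray(loadings, dtype=float).T  # p x k
    if normalize:
        h = np.linalg.norm(A, axis=1, keepdims=True)
        A = np.divide(A, h, out=np.zeros_like(A), where=h > 0)
    sq = A**2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-8,
    max_sweeps: int = 500,
) -> np.ndarray:
    """Orthogonally rotate ``k x p`` loadings to maximize the varimax
    criterion.

    Uses the classical pairwise planar-rotation sweeps: for each pair of
    factors the criterion has a closed-form optimal angle; sweeps repeat
    until the criterion gains less than ``tol`` or ``max_sweeps`` is
    reached. With ``normalize`` the rows of the variables-by-factors matrix
    are scaled to unit length during optimization (Kaiser normalization)
    and restored afterwards. The rotation is orthogonal, so the Frobenius
    norm of the loadings is preserved. ``k = 1`` returns the input
    unchanged (any rotation of one factor is a sign flip).
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise ParameterError("loadings must be 2-D (factors x variables)")
    k, p = L.shape
    if k == 1:
        return L.copy()

    A = L.T.copy()  # p x k, variables in rows
    if normalize:
        h = np.linalg.norm(A, axis=1, keepdims=True)
        scale = np.where(h > 0, h, 1.0)
        A /= scale

    crit = varimax_criterion(A.T, normalize=False)
    for _ in range(max_sweeps):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = A[:, i], A[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (u @ v - u.sum() * v.sum() / p)
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                theta = 0.25 * np.arctan2(num, den)
                if abs(theta) < 1e-12:
                    continue
                c, s = np.cos(theta), np.sin(theta)
                A[:, i], A[:, j] = c * x + s * y, -s * x + c * y
        new_crit = varimax_criterion(A.T, normalize=False)
        if new_crit - crit < tol:
            break
        crit = new_crit

    if normalize:
        A *= scale
    return A.T


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each row so its maximum-|value| entry is positive (loading sign
    is not identified: the clustering distance uses |cosine|)."""
    out = loadings.copy()
    for row in out:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return out


def extract_pcs(sm: SubjectMatrix | np.ndarray, subject_id: str | None = None) -> PCSet:
    """Extract the retained, varimax-rotated loading vectors of one subject.

    Accepts a :class:`SubjectMatrix` or a plain ``frames x 17`` array. PCA
    runs on the correlation matrix, so the result is invariant to positive
    per-column rescaling of the input.

    Raises
    ------
    DegenerateRetentionError
        If no eigenvalue exceeds 1 (e.g. uncorrelated input).
    DataError
        On non-finite input or fewer rows than joints.
    """
    if isinstance(sm, SubjectMatrix):
        data = sm.data
        subject_id = subject_id or sm.subject_id
    else:
        data = np.asarray(sm, dtype=float)
        subject_id = subject_id or ""
    if data.ndim != 2 or data.shape[1] != N_JOINTS:
        raise DataError(f"expected frames x {N_JOINTS} matrix, got {data.shape}")
    if data.shape[0] < N_JOINTS:
        raise DataError("need at least as many frames as joints")
    if not np.isfinite(data).all():
        raise DataError("non-finite values in subject matrix")

    corr = np.corrcoef(data, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    retained = eigval > 1.0  # strict: ties at exactly 1 are excluded
    if not retained.any():
        raise DegenerateRetentionError(
            f"subject {subject_id!r}: no eigenvalue exceeds 1 "
            f"(max {eigval[0]:.6f})"
        )
    ev = eigval[retained]
    # factor loadings: eigenvectors scaled by sqrt(eigenvalue)
    factors = (eigvec[:, retained] * np.sqrt(ev)).T  # k x 17
    rotated = varimax_rotate(factors, normalize=True)
    norms = np.linalg.norm(rotated, axis=1, keepdims=True)
    unit = _fix_signs(rotated / norms)
    return PCSet(
        subject_id=subject_id,
        loadings=unit,
        eigenvalues=ev,
        variance_explained=float(ev.sum() / N_JOINTS),
    )


@dataclass
class CohortSummary:
    """Per-subject retention/variance table plus cohort aggregates."""

    table: pd.DataFrame  # subject_id, k, variance_explained
    k_counts: dict[int, int]
    variance_mean: float
    variance_sd: float  # sample SD (ddof=1); 0 for a single subject


def cohort_summary(pcsets: list[PCSet]) -> CohortSummary:
    """Summarize retention counts and variance explained across subjects."""
    if not pcsets:
        raise ParameterError("cohort_summary needs at least one PCSet")
    table = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in pcsets],
            "k": [p.k for p in pcsets],
            "variance_explained": [p.variance_explained for p in pcsets],
        }
    )
    var = table["variance_explained"].to_numpy()
    ks = table["k"].value_counts().sort_index()
    return CohortSummary(
        table=table,
        k_counts={int(k): int(c) for k, c in ks.items()},
        variance_mean=float(var.mean()),
        variance_sd=float(var.std(ddof=1)) if len(var) > 1 else 0.0,
    )


def pcsets_to_frame(pcsets: list[PCSet]) -> pd.DataFrame:
    """Flatten PC sets into one row per retained PC (the clustering input):
    subject_id, pc_index, eigenvalue, then the 17 loading columns."""
    rows = []
    for p in pcsets:
        for i in range(p.k):
            row = {
                "subject_id": p.subject_id,
                "pc_index": i,
                "eigenvalue": p.eigenvalues[i],
            }
            row.update(dict(zip(JOINT_NAMES, p.loadings[i])))
            rows.append(row)
    return pd.DataFrame(rows)


def pcsets_from_frame(df: pd.DataFrame) -> list[PCSet]:
    """Inverse of :func:`pcsets_to_frame` (variance recomputed from the
    stored eigenvalues)."""
    pcsets = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("pc_index")
        ev = grp["eigenvalue"].to_numpy(dtype=float)
        pcsets.append(
            PCSet(
                subject_id=str(sid),
                loadings=grp[list(JOINT_NAMES)].to_numpy(dtype=float),
                eigenvalues=ev,
                variance_explained=float(ev.sum() / N_JOINTS),
            )
        )
    return pcsets
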