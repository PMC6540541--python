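"""Pooling and clustering of loading vectors into cluster-level synergies.

All subjects' retained PCs are pooled into one set of N unit loading
vectors. The dissimilarity between two loadings is the angle between the
*lines* they span,

    d(i, j) = arccos( |PCL_i . PCL_j| / (||PCL_i|| ||PCL_j||) )   (degrees)

bounded by 90 deg — the modulus makes the sign of a loading irrelevant,
as it should be for a covariation pattern. The N x N angle matrix feeds
complete-linkage agglomerative clustering; the flat clustering is taken at
the largest gap between consecutive dendrogram merge heights (cut
immediately below the merge that opens the gap). Each cluster's share of
the total variance is defined by count — PCs in the cluster over total
pooled PCs — and the synergy set is the smallest prefix of clusters, in
descending variance share, that accounts for at least 80% of the pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DataError, ParameterError
from .extraction import PCSet

__all__ = [
    "PCPool",
    "ClusterInfo",
    "SynergyCatalog",
    "pairwise_angle",
    "complete_linkage",
    "select_cut",
    "cluster_variance",
    "select_synergies",
    "characterize_cluster",
    "build_catalog",
]


@dataclass
class PCPool:
    """All retained loading vectors of a cohort with provenance."""

    vectors: np.ndarray  # N x 17, unit rows
    provenance: list[tuple[str, int]]  # (subject_id, pc_index) per row

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(self.provenance) != self.vectors.shape[0]:
            raise ParameterError("provenance must have one entry per vector")
        norms = np.linalg.norm(self.vectors, axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-9)
        if bad.size:
            sid, idx = self.provenance[bad[0]]
            raise DataError(
                f"loading vector of subject {sid!r} (pc {idx}) is not unit "
                f"norm ({norms[bad[0]]:.3e})"
            )

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @classmethod
    def from_pcsets(cls, pcsets: list[PCSet]) -> "PCPool":
        vectors = np.concatenate([p.loadings for p in pcsets])
        prov = [(p.subject_id, i) for p in pcsets for i in range(p.k)]
        return cls(vectors=vectors, provenance=prov)


def pairwise_angle(pool: PCPool | np.ndarray) -> np.ndarray:
    """N x N matrix of line angles (degrees) between loading vectors.

    Symmetric, zero diagonal, entries in [0, 90]; the cosine argument is
    clamped to [0, 1] so rounding can never push arccos out of domain.
    """
    V = pool.vectors if isinstance(pool, PCPool) else np.asarray(pool, dtype=float)
    if V.shape[0] < 2:
        raise ParameterError("need at least 2 vectors")
    norms = np.linalg.norm(V, axis=1)
    zero = np.flatnonzero(norms < 1e-12)
    if zero.size:
        where = (
            f"subject {pool.provenance[zero[0]][0]!r} pc {pool.provenance[zero[0]][1]}"
            if isinstance(pool, PCPool)
            else f"row {zero[0]}"
        )
        raise DataError(f"zero-norm loading vector ({where})")
    cos = np.abs(V @ V.T) / np.outer(norms, norms)
    np.clip(cos, 0.0, 1.0, out=cos)
    deg = np.degrees(np.arccos(cos))
    deg = 0.5 * (deg + deg.T)
    np.fill_diagonal(deg, 0.0)
    return deg


def complete_linkage(dist: np.ndarray) -> np.ndarray:
    """Agglomerate with complete linkage (inter-cluster distance = maximum
    pairwise member distance). Returns the (N-1) x 4 merge table in scipy
    linkage format; merge heights are non-decreasing."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ParameterError(f"distance matrix must be square, got {dist.shape}")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ParameterError("distance matrix must be symmetric")
    return linkage(squareform(dist, checks=False), method="complete")


def select_cut(tree: np.ndarray) -> tuple[float, np.ndarray]:
    """Choose the flat clustering at the largest merge-height gap.

    Scans consecutive dendrogram merge heights, finds the largest jump
    (earliest on ties) and cuts immediately below the merge that opens it.
    Returns ``(cut_distance, labels)`` with 0-based cluster labels. All
    heights equal → no gap → error (caller must supply an explicit cut).
    """
    tree = np.asarray(tree, dtype=float)
    if tree.shape[0] < 2:
        raise ParameterError("need at least 2 merges to locate a gap")
    heights = tree[:, 2]
    gaps = np.diff(heights)
    if np.all(gaps <= 1e-12):
        raise DataError("all merge heights equal: no gap to cut at")
    i = int(np.argmax(gaps))
    cut = float(0.5 * (heights[i] + heights[i + 1]))
    return cut, cut_tree_at(tree, cut)


def cut_tree_at(tree: np.ndarray, cut: float) -> np.ndarray:
    """Flat 0-based cluster labels at an explicit cut height (degrees)."""
    return fcluster(tree, t=cut, criterion="distance") - 1


def cluster_variance(labels: np.ndarray) -> np.ndarray:
    """Count-based variance fraction per cluster: |cluster| / N.

    Indexed by cluster label; fractions sum to 1 exactly up to rounding.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels)
    return counts / labels.size


def select_synergies(fractions: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Minimal prefix of clusters, by descending variance fraction, whose
    cumulative fraction reaches ``threshold``. Ties keep the smaller
    cluster index first. Returns the selected cluster indices in order."""
    if not 0 < threshold <= 1:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    fractions = np.asarray(fractions, dtype=float)
    order = np.argsort(-fractions, kind="stable")
    csum = np.cumsum(fractions[order])
    n_sel = int(np.searchsorted(csum, threshold - 1e-12) + 1)
    n_sel = min(n_sel, len(order))
    return order[:n_sel]


def characterize_cluster(
    vectors: np.ndarray, subject_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sign-aligned mean and SD of a cluster's loading vectors.

    The reference member is the one with the largest total |dot| to all
    members; every member is flipped to have a nonnegative dot with it
    (averaging is sign-sensitive even though the clustering distance is
    not). Returns ``(mean_loading, sd_loading, n_subjects)`` with the SD
    per joint (population SD) and the count of *distinct* subjects.
    """
    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2 or V.shape[0] < 1:
        raise ParameterError("need at least one member vector")
    G = V @ V.T
    ref = int(np.argmax(np.abs(G).sum(axis=1)))
    signs = np.where(G[:, ref] < 0, -1.0, 1.0)
    aligned = V * signs[:, None]
    return aligned.mean(axis=0), aligned.std(axis=0), len(set(subject_ids))


@dataclass
class ClusterInfo:
    """One cluster of pooled PCs and its summary statistics."""

    members: list[int]  # row indices into the pool
    variance_fraction: float
    mean_loading: np.ndarray
    sd_loading: np.ndarray
    n_subjects: int  # distinct subjects contributing
    n_pcs: int  # total member PCs (>= n_subjects)


@dataclass
class SynergyCatalog:
    """Clustered pool: clusters in descending variance fraction, the cut,
    and the selected synergy prefix (cumulative fraction >= threshold)."""

    cut_distance: float
    threshold: float
    clusters: list[ClusterInfo]
    selected: list[int]  # indices into ``clusters``
    provenance: list[tuple[str, int]]
    merges: np.ndarray  # scipy linkage table, for dendrogram export

    @property
    def n_pool(self) -> int:
        return len(self.provenance)

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["merges"] = np.asarray(self.merges).tolist()
        for c in doc["clusters"]:
            c["mean_loading"] = list(map(float, c["mean_loading"]))
            c["sd_loading"] = list(map(float, c["sd_loading"]))
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SynergyCatalog":
        doc = json.loads(Path(path).read_text())
        clusters = [
            ClusterInfo(
                members=c["members"],
                variance_fraction=c["variance_fraction"],
                mean_loading=np.asarray(c["mean_loading"]),
                sd_loading=np.asarray(c["sd_loading"]),
                n_subjects=c["n_subjects"],
                n_pcs=c["n_pcs"],
            )
            for c in doc["clusters"]
        ]
        return cls(
            cut_distance=doc["cut_distance"],
            threshold=doc["threshold"],
            clusters=clusters,
            selected=doc["selected"],
            provenance=[tuple(p) for p in doc["provenance"]],
            merges=np.asarray(doc["merges"], dtype=float),
        )


def build_catalog(
    pool: PCPool, threshold: float = 0.8, cut: float | None = None
) -> SynergyCatalog:
    """Run the whole clustering stage on a pooled PC set.

    ``cut`` (degrees) overrides the automatic largest-gap rule. Clusters
    are ordered by descending variance fraction (stable on ties).
    """
    dist = pairwise_angle(pool)
    tree = complete_linkage(dist)
    if cut is None:
        cut, labels = select_cut(tree)
    else:
        labels = cut_tree_at(tree, cut)
    fractions = cluster_variance(labels)
    order = np.argsort(-fractions, kind="stable")

    clusters: list[ClusterInfo] = []
    for lab in order:
        members = np.flatnonzero(labels == lab)
        sids = [pool.provenance[m][0] for m in members]
        mean, sd, n_subj = characterize_cluster(pool.vectors[members], sids)
        clusters.append(
            ClusterInfo(
                members=[int(m) for m in members],
                variance_fraction=float(fractions[lab]),
                mean_loading=mean,
                sd_loading=sd,
                n_subjects=n_subj,
                n_pcs=int(members.size),
            )
        )
    sel = select_synergies(
        np.array([c.variance_fraction for c in clusters]), threshold
    )
    # clusters are already sorted, so the selection is a prefix
    selected = sorted(int(i) for i in sel)
    return SynergyCatalog(
        cut_distance=float(cut),
        threshold=float(threshold),
        clusters=clusters,
        selected=selected,
        provenance=list(pool.provenance),
        merges=tree,
    )
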