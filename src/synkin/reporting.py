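"""Machine-readable result surfaces: per-subject histograms, cluster
variance, synergy loading tables and subject prevalence.

Every table is recomputable from the PC sets and the catalog alone; plots
are optional (matplotlib is imported lazily so headless pipelines never
require it)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import SynergyCatalog
from .errors import ParameterError
from .extraction import PCSet, cohort_summary
from .schema import JOINT_NAMES

__all__ = ["ReportBundle", "build_report", "write_report", "plot_report"]


@dataclass
class ReportBundle:
    """Deterministic result tables of one cohort analysis."""

    subject_table: pd.DataFrame  # subject_id, k, variance_explained
    k_histogram: pd.DataFrame  # k, n_subjects
    variance_summary: pd.DataFrame  # mean, sd (sample) of variance explained
    cluster_variance: pd.DataFrame  # cluster, variance_fraction, n_pcs, n_subjects, selected
    synergy_loadings: pd.DataFrame  # synergy, joint, mean, sd (17 rows per selected synergy)
    prevalence: pd.DataFrame  # cluster, n_subjects, n_pcs


def build_report(pcsets: list[PCSet], catalog: SynergyCatalog) -> ReportBundle:
    """Assemble all result tables from the extraction and clustering output.

    Raises
    ------
    ParameterError
        If the catalog's provenance references subjects absent from
        ``pcsets`` (the two inputs must come from the same cohort run).
    """
    pc_subjects = {p.subject_id for p in pcsets}
    offenders = sorted({s for s, _ in catalog.provenance} - pc_subjects)
    if offenders:
        raise ParameterError(
            "catalog references unknown subject(s): " + ", ".join(offenders)
        )

    summ = cohort_summary(pcsets)
    k_hist = pd.DataFrame(
        sorted(summ.k_counts.items()), columns=["k", "n_subjects"]
    )
    var_summary = pd.DataFrame(
        {"mean_variance_explained": [summ.variance_mean],
         "sd_variance_explained": [summ.variance_sd]}
    )
    selected = set(catalog.selected)
    cluster_rows = [
        {
            "cluster": i,
            "variance_fraction": c.variance_fraction,
            "n_pcs": c.n_pcs,
            "n_subjects": c.n_subjects,
            "selected": i in selected,
        }
        for i, c in enumerate(catalog.clusters)
    ]
    cluster_df = pd.DataFrame(cluster_rows)

    loading_rows = []
    for i in catalog.selected:
        c = catalog.clusters[i]
        for j, name in enumerate(JOINT_NAMES):
            loading_rows.append(
                {
                    "synergy": i,
                    "joint": name,
                    "mean_loading": c.mean_loading[j],
                    "sd_loading": c.sd_loading[j],
                }
            )
    loadings_df = pd.DataFrame(loading_rows)

    prevalence_df = pd.DataFrame(
        {
            "cluster": np.arange(len(catalog.clusters)),
            "n_subjects": [c.n_subjects for c in catalog.clusters],
            "n_pcs": [c.n_pcs for c in catalog.clusters],
        }
    )
    return ReportBundle(
        subject_table=summ.table,
        k_histogram=k_hist,
        variance_summary=var_summary,
        cluster_variance=cluster_df,
        synergy_loadings=loadings_df,
        prevalence=prevalence_df,
    )


_TABLES = (
    "subject_table",
    "k_histogram",
    "variance_summary",
    "cluster_variance",
    "synergy_loadings",
    "prevalence",
)


def write_report(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write every table as ``<name>.csv`` under ``outdir``; deterministic
    byte-for-byte for identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _TABLES:
        path = outdir / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False, float_format="%.12g")
        written.append(path)
    return written


def plot_report(
    bundle: ReportBundle, catalog: SynergyCatalog, outdir: str | Path
) -> list[Path]:
    """Render the standard figures (retention histogram, variance-per-
    cluster bars, per-synergy loading bars with SD whiskers, dendrogram)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].bar(bundle.k_histogram["k"], bundle.k_histogram["n_subjects"])
    axes[0].set_xlabel("retained PCs")
    axes[0].set_ylabel("subjects")
    axes[1].hist(bundle.subject_table["variance_explained"] * 100, bins=10)
    axes[1].set_xlabel("% variance explained")
    fig.tight_layout()
    p = outdir / "retention_histograms.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(7, 3.5))
    cv = bundle.cluster_variance
    ax.bar(cv["cluster"], cv["variance_fraction"] * 100)
    ax.set_xlabel("cluster")
    ax.set_ylabel("% of pooled PCs")
    fig.tight_layout()
    p = outdir / "cluster_variance.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    n_sel = len(catalog.selected)
    if n_sel:
        fig, axes = plt.subplots(n_sel, 1, figsize=(8, 2.2 * n_sel), squeeze=False)
        x = np.arange(len(JOINT_NAMES))
        for ax, i in zip(axes[:, 0], catalog.selected):
            c = catalog.clusters[i]
            ax.bar(x, c.mean_loading, yerr=c.sd_loading, capsize=2)
            ax.set_xticks(x)
            ax.set_xticklabels(JOINT_NAMES, rotation=90, fontsize=6)
            ax.set_ylabel(f"synergy {i}")
        fig.tight_layout()
        p = outdir / "synergy_loadings.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(catalog.merges, ax=ax, no_labels=True, color_threshold=catalog.cut_distance)
    ax.axhline(catalog.cut_distance, ls="--", c="k", lw=0.8)
    ax.set_ylabel("angle (deg)")
    fig.tight_layout()
    p = outdir / "dendrogram.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
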