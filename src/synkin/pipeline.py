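"""End-to-end convenience wrapper: recordings → PC sets → synergy catalog."""

from __future__ import annotations

from .clustering import PCPool, SynergyCatalog, build_catalog
from .extraction import PCSet, extract_pcs
from .preprocessing import preprocess_recording
from .schema import JointAngleRecording

__all__ = ["run_study"]


def run_study(
    recordings: list[JointAngleRecording],
    cutoff: float = 5.0,
    order: int = 2,
    n_frames: int = 1000,
    threshold: float = 0.8,
    cut: float | None = None,
) -> tuple[list[PCSet], SynergyCatalog]:
    """Run the full analysis on a cohort of labeled recordings.

    Per subject: segment, low-pass filter (zero-phase Butterworth), rescale
    each repetition to ``n_frames``, pool and standardize, extract PCs
    (Kaiser retention + varimax). Then pool all loadings, cluster by line
    angle with complete linkage, cut at the largest height gap (or an
    explicit ``cut`` in degrees), and select the synergy prefix reaching
    ``threshold`` of the pooled-PC count.
    """
    pcsets = [
        extract_pcs(preprocess_recording(rec, cutoff=cutoff, order=order, n_frames=n_frames))
        for rec in recordings
    ]
    catalog = build_catalog(PCPool.from_pcsets(pcsets), threshold=threshold, cut=cut)
    return pcsets, catalog
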