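"""Off-target QC: depth-matched pseudobulk comparison of two libraries.

Depletion globally re-allocates reads, so size-factor-normalising
differential-expression tools mask both the benefit and the off-targets;
the comparison here is deliberately naive: sum each condition to a
pseudobulk, downsample the larger to the smaller's depth, and compare
per-gene log2 fold changes directly.  No size-factor normalisation is
offered.  Coordinate-overlap genes (spans intersecting panel targets)
are separated from sequence-similarity off-target candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CountMatrix, GeneAnnotation
from .target_selection import DEFAULT_FLANK, TargetPanel

logger = logging.getLogger("scdeplete")

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_FLAG_THRESHOLD = -0.5


@dataclass
class PseudobulkComparison:
    """Per-gene control vs treated pseudobulk counts at matched depth."""

    gene_ids: list[str]
    control_counts: np.ndarray
    treated_counts: np.ndarray
    log2fc: np.ndarray
    r_squared: float
    depth: int
    pseudocount: float
    panel_mask: np.ndarray = field(repr=False, default=None)


def pseudobulk(matrix: CountMatrix) -> np.ndarray:
    """Per-gene totals across all cells, in gene order."""
    return matrix.counts.sum(axis=1)


def _downsample_bulk(totals: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    current = int(totals.sum())
    if current <= depth:
        return totals.astype(np.int64)
    return rng.multinomial(depth, totals / current).astype(np.int64)


def depth_matched_log2fc(
    control: CountMatrix,
    treated: CountMatrix,
    panel: TargetPanel | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
) -> PseudobulkComparison:
    """Pseudobulk both conditions, match depth, and compute per-gene log2FC.

    The larger pseudobulk is multinomially downsampled to the smaller
    total; log2fc = log2((treated + c) / (control + c)).  r^2 is the
    least-squares fit of log2(treated + c) on log2(control + c) over
    non-panel genes (all genes when no panel is given).
    """
    shared = [g for g in control.gene_ids if g in set(treated.gene_ids)]
    if not shared:
        raise ValueError("control and treated share no genes")
    c_idx = control.gene_index(shared)
    t_idx = treated.gene_index(shared)
    c_bulk = pseudobulk(control)[c_idx]
    t_bulk = pseudobulk(treated)[t_idx]

    depth = int(min(c_bulk.sum(), t_bulk.sum()))
    rng = np.random.default_rng(seed)
    c_bulk = _downsample_bulk(c_bulk, depth, rng)
    t_bulk = _downsample_bulk(t_bulk, depth, rng)

    log_c = np.log2(c_bulk + pseudocount)
    log_t = np.log2(t_bulk + pseudocount)
    log2fc = log_t - log_c

    panel_mask = np.zeros(len(shared), dtype=bool)
    if panel is not None:
        panel_genes = panel.gene_set()
        panel_mask = np.array([g in panel_genes for g in shared])
    x, y = log_c[~panel_mask], log_t[~panel_mask]
    if len(x) >= 2 and x.std() > 0 and y.std() > 0:
        r_squared = float(np.corrcoef(x, y)[0, 1] ** 2)
    else:
        r_squared = 1.0 if np.allclose(x, y) else 0.0
    return PseudobulkComparison(
        gene_ids=shared,
        control_counts=c_bulk,
        treated_counts=t_bulk,
        log2fc=log2fc,
        r_squared=r_squared,
        depth=depth,
        pseudocount=pseudocount,
        panel_mask=panel_mask,
    )


def flag_offtargets(
    comparison: PseudobulkComparison,
    panel: TargetPanel | None = None,
    threshold: float = DEFAULT_FLAG_THRESHOLD,
) -> list[tuple[str, float]]:
    """Non-panel genes depleted below the log2FC threshold, most depleted first."""
    if panel is not None:
        panel_genes = panel.gene_set()
        mask = np.array([g in panel_genes for g in comparison.gene_ids])
    else:
        mask = comparison.panel_mask
    flagged = [
        (g, float(fc))
        for g, fc, in_panel in zip(comparison.gene_ids, comparison.log2fc, mask)
        if not in_panel and fc < threshold
    ]
    flagged.sort(key=lambda t: t[1])
    return flagged


def coordinate_overlap_genes(
    panel: TargetPanel,
    annotation: GeneAnnotation,
    flank: int = DEFAULT_FLANK,
) -> list[str]:
    """Non-panel genes whose span intersects any panel target region.

    Panel gene spans are extended by the depletion flank (matching the
    depletion reference); panel intervals are used as-is.  A non-panel
    gene overlapping either is expected to lose counts for coordinate
    reasons rather than guide-sequence similarity.
    """
    panel_genes = panel.gene_set()
    targets: list[tuple[str, int, int]] = []
    for g in panel_genes:
        if g in annotation:
            rec = annotation.genes[g]
            targets.append((rec.contig, max(0, rec.start - flank), rec.end + flank))
    targets.extend(panel.intervals)

    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in targets:
        by_contig.setdefault(contig, []).append((s, e))

    out = []
    for gid, rec in annotation.genes.items():
        if gid in panel_genes:
            continue
        spans = by_contig.get(rec.contig, [])
        if any(s < rec.end and e > rec.start for s, e in spans):
            out.append(gid)
    return sorted(out)


def offtarget_report(
    comparison: PseudobulkComparison,
    panel: TargetPanel,
    annotation: GeneAnnotation,
    threshold: float = DEFAULT_FLAG_THRESHOLD,
    flank: int = DEFAULT_FLANK,
) -> dict[str, object]:
    """Partition flagged genes into coordinate-overlap vs sequence-similarity.

    Genes flagged by log2FC that also overlap a panel target region are
    attributable to coordinate overlap; the remainder are reported as
    sequence-similarity off-target candidates.
    """
    flagged = flag_offtargets(comparison, panel, threshold)
    overlap = set(coordinate_overlap_genes(panel, annotation, flank))
    return {
        "threshold": threshold,
        "r_squared": comparison.r_squared,
        "flagged": flagged,
        "coordinate_overlap": [(g, fc) for g, fc in flagged if g in overlap],
        "sequence_similarity_candidates": [(g, fc) for g, fc in flagged if g not in overlap],
    }
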