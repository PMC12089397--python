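"""In-silico depletion at read level and count level.

The model assumes complete (100%-efficiency) removal of targeted
material: every read or UMI attributable to a panel target is deleted,
and sequencing a depleted library is mimicked by resampling to a matched
depth.  At count level removed molecules are replaced by a fresh
multinomial draw over the remaining genes, proportional to each gene's
relative abundance in that cell - so for a targeted UMI share f the
expected fold-increase of informative (non-targeted) molecules at
matched depth is 1/(1-f).

Read classification against the depletion reference uses canonical
k-mer containment (k = 21, containment threshold 0.5 by default), a
deterministic desk-scale stand-in for spliced alignment; an externally
produced read->label table can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    BarcodedReadSet,
    ConfigurationError,
    CountMatrix,
    SequenceSet,
    reverse_complement,
)
from .target_selection import TargetPanel

logger = logging.getLogger("scdeplete")

DEFAULT_K = 21
DEFAULT_THETA = 0.5
DEFAULT_CATEGORY_ORDER = ("gene", "interval", "rrna")

TARGETED_LABELS = ("targeted_gene", "targeted_interval", "targeted_rrna")
RETAINED = "retained"


@dataclass
class ReadClassification:
    """Per-read depletion label and the matcher parameters that produced it."""

    labels: dict[str, str]
    k: int = DEFAULT_K
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        valid = set(TARGETED_LABELS) | {RETAINED}
        for rid, label in self.labels.items():
            if label not in valid:
                raise ValueError(f"read {rid}: unknown label {label!r}")

    def n_targeted(self) -> int:
        return sum(1 for v in self.labels.values() if v != RETAINED)

    def category_counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in TARGETED_LABELS}
        for v in self.labels.values():
            if v != RETAINED:
                out[v] += 1
        return out


@dataclass
class DepletionSummary:
    """Before/after bookkeeping for one depletion run.

    ``reads_before``/``reads_after`` count reads (read-level runs) or UMIs
    (count-level runs).  ``category_fractions`` sum to ``fraction_removed``.
    ``informative_fold_change`` is the after/before ratio of non-targeted
    molecules at matched depth.
    """

    reads_before: int
    reads_after: int
    fraction_removed: float
    category_fractions: dict[str, float] = field(default_factory=dict)
    informative_fold_change: float = 1.0
    per_cell_depth: int | str | None = None
    cells_dropped: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.reads_after > self.reads_before:
            raise ValueError("reads_after exceeds reads_before")
        total = sum(self.category_fractions.values())
        if self.category_fractions and abs(total - self.fraction_removed) > 1e-9:
            raise ValueError("category fractions do not sum to fraction_removed")


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Distinct strand-insensitive k-mers of a sequence."""
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        out.add(min(kmer, reverse_complement(kmer)))
    return out


def classify_reads(
    reads: BarcodedReadSet,
    references: dict[str, SequenceSet],
    k: int = DEFAULT_K,
    theta: float = DEFAULT_THETA,
    category_order: tuple[str, ...] = DEFAULT_CATEGORY_ORDER,
) -> ReadClassification:
    """Label each read by canonical k-mer containment against the references.

    A read gets the first category (default order gene > interval > rRNA)
    whose reference shares at least ``theta`` of the read's distinct
    canonical k-mers; otherwise it is retained.  Deterministic.
    """
    if not 0 < theta <= 1:
        raise ConfigurationError("theta must be in (0, 1]")
    ref_kmers: dict[str, set[str]] = {}
    for cat in category_order:
        kmers: set[str] = set()
        for _, seq in references.get(cat, SequenceSet()).items():
            kmers |= canonical_kmers(seq, k)
        ref_kmers[cat] = kmers

    labels: dict[str, str] = {}
    for pair in reads:
        if len(pair.cdna) < k:
            raise ConfigurationError(
                f"read {pair.read_id}: cDNA shorter than k ({len(pair.cdna)} < {k})"
            )
        read_kmers = canonical_kmers(pair.cdna, k)
        label = RETAINED
        for cat in category_order:
            shared = len(read_kmers & ref_kmers[cat])
            if shared >= theta * len(read_kmers):
                label = f"targeted_{cat}"
                break
        labels[pair.read_id] = label
    return ReadClassification(labels, k, theta)


def deplete_reads(reads: BarcodedReadSet, classification: ReadClassification) -> BarcodedReadSet:
    """Remove every targeted read; retained reads keep their order."""
    missing = [p.read_id for p in reads if p.read_id not in classification.labels]
    if missing:
        raise ValueError(f"classification does not cover reads: {missing[:5]}...")
    kept = [p for p in reads if classification.labels[p.read_id] == RETAINED]
    return BarcodedReadSet(kept, reads.barcode_len, reads.umi_len)


def downsample_pairs(reads: BarcodedReadSet, n: int, seed: int) -> BarcodedReadSet:
    """Uniform sample of n read pairs without replacement, order-preserving."""
    if n > len(reads):
        raise ValueError(f"cannot sample {n} pairs from {len(reads)} reads")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return BarcodedReadSet([reads.pairs[i] for i in idx], reads.barcode_len, reads.umi_len)


def deplete_counts(
    matrix: CountMatrix,
    panel: TargetPanel,
    per_cell_depth: int | str = "match",
    seed: int = 0,
) -> tuple[CountMatrix, DepletionSummary]:
    """Count-level depletion with multinomial re-allocation.

    Panel-gene counts are zeroed in every cell; each cell's counts are then
    redrawn as a multinomial of size ``per_cell_depth`` (the cell's
    original total when "match") over non-panel genes, with probabilities
    proportional to the cell's original non-panel counts.  Cells left with
    no non-panel counts are dropped.
    """
    if per_cell_depth != "match":
        if not isinstance(per_cell_depth, (int, np.integer)) or per_cell_depth <= 0:
            raise ConfigurationError("per_cell_depth must be a positive integer or 'match'")

    panel_genes = panel.gene_set()
    absent = panel_genes - set(matrix.gene_ids)
    if absent:
        logger.warning("%d panel genes absent from matrix gene namespace", len(absent))
    panel_idx = matrix.gene_index(panel_genes)
    panel_mask = np.zeros(matrix.n_genes, dtype=bool)
    panel_mask[panel_idx] = True

    rng = np.random.default_rng(seed)
    counts = matrix.counts
    totals = counts.sum(axis=0)
    nonpanel_before = counts[~panel_mask, :].sum(axis=0)

    new_cols: list[np.ndarray] = []
    kept_cells: list[int] = []
    for c in range(matrix.n_cells):
        nonpanel = counts[:, c].astype(np.float64)
        nonpanel[panel_mask] = 0.0
        s = nonpanel.sum()
        if s == 0:
            logger.warning("cell %s has no non-panel counts; dropped", matrix.cell_barcodes[c])
            continue
        depth = int(totals[c]) if per_cell_depth == "match" else int(per_cell_depth)
        new_cols.append(rng.multinomial(depth, nonpanel / s))
        kept_cells.append(c)

    if not kept_cells:
        raise ValueError("all cells were emptied by depletion")
    new_counts = np.column_stack(new_cols).astype(np.int64)
    depleted = CountMatrix(
        new_counts,
        list(matrix.gene_ids),
        [matrix.cell_barcodes[c] for c in kept_cells],
    )

    kept = np.array(kept_cells, dtype=int)
    before_total = int(totals[kept].sum())
    removed_total = before_total - int(nonpanel_before[kept].sum())
    cat_fracs: dict[str, float] = {}
    for cat, genes in panel.categories.items():
        idx = matrix.gene_index(genes)
        cat_fracs[cat] = float(counts[np.ix_(idx, kept)].sum()) / before_total if len(idx) else 0.0

    if per_cell_depth == "match":
        after_nonpanel = int(new_counts.sum())
        fold = after_nonpanel / int(nonpanel_before[kept].sum())
    else:
        # fold change is defined at matched depth: compare per-molecule shares
        fold = 1.0 / (1.0 - removed_total / before_total) if removed_total else 1.0

    summary = DepletionSummary(
        reads_before=before_total,
        reads_after=before_total - removed_total,
        fraction_removed=removed_total / before_total,
        category_fractions=cat_fracs,
        informative_fold_change=float(fold),
        per_cell_depth=per_cell_depth,
        cells_dropped=matrix.n_cells - len(kept_cells),
        seed=seed,
    )
    return depleted, summary


def summarize_depletion(
    before: BarcodedReadSet | CountMatrix,
    after: BarcodedReadSet | CountMatrix,
    classification: ReadClassification | None = None,
    panel: TargetPanel | None = None,
    matched_depth: bool = True,
) -> DepletionSummary:
    """Fill a DepletionSummary from matched before/after inputs.

    For read sets a classification is required; category fractions come
    from the labels and the informative fold change at matched depth is
    1/(1 - fraction_removed).  For count matrices a panel is required and
    the fold change compares non-panel UMIs over the surviving cells.
    """
    if isinstance(before, BarcodedReadSet):
        if classification is None:
            raise ValueError("read-level summary requires a classification")
        n_before, n_after = len(before), len(after)
        cats = classification.category_counts()
        removed = classification.n_targeted()
        if n_before - n_after != removed:
            raise ValueError("after read count inconsistent with classification")
        frac = removed / n_before if n_before else 0.0
        fold = 1.0 / (1.0 - frac) if frac < 1 else float("inf")
        return DepletionSummary(
            reads_before=n_before,
            reads_after=n_after,
            fraction_removed=frac,
            category_fractions={k: v / n_before for k, v in cats.items()} if n_before else {},
            informative_fold_change=fold,
        )

    if panel is None:
        raise ValueError("count-level summary requires a panel")
    surviving = [b for b in after.cell_barcodes if b in set(before.cell_barcodes)]
    b_idx = {b: i for i, b in enumerate(before.cell_barcodes)}
    a_idx = {b: i for i, b in enumerate(after.cell_barcodes)}
    bi = np.array([b_idx[b] for b in surviving], dtype=int)
    ai = np.array([a_idx[b] for b in surviving], dtype=int)

    panel_mask = np.zeros(before.n_genes, dtype=bool)
    panel_mask[before.gene_index(panel.gene_set())] = True

    before_tot = int(before.counts[:, bi].sum())
    after_tot = int(after.counts[:, ai].sum())
    if before_tot != after_tot and not matched_depth:
        raise ValueError("before/after totals differ and matched_depth is not set")

    nonpanel_before = int(before.counts[np.ix_(~panel_mask, bi)].sum())
    nonpanel_after = int(after.counts[np.ix_(~panel_mask, ai)].sum())
    removed = before_tot - nonpanel_before
    cat_fracs = {
        cat: float(before.counts[np.ix_(before.gene_index(genes), bi)].sum()) / before_tot
        if len(before.gene_index(genes))
        else 0.0
        for cat, genes in panel.categories.items()
    }
    return DepletionSummary(
        reads_before=before_tot,
        reads_after=before_tot - removed,
        fraction_removed=removed / before_tot,
        category_fractions=cat_fracs,
        informative_fold_change=(nonpanel_after / nonpanel_before) if nonpanel_before else float("inf"),
        per_cell_depth="match" if matched_depth else None,
        cells_dropped=before.n_cells - len(surviving),
    )
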