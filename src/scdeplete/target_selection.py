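"""Curation of the removal-target categories and panel assembly.

Four categories of molecules are curated for depletion from 3' scRNA-seq
libraries: ribosomal RNA genes (rRNA), mitochondrially-encoded genes
(mito), nuclear ribosomal protein-coding genes (ribo), and non-variable
genes (NVG) - highly expressed, low-variance protein-coding genes whose
removal frees sequencing depth without discarding cell-type information.
A fifth component is a set of abundantly covered intergenic genomic
windows.  The assembled panel drives both guide design and in-silico
depletion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    ConfigurationError,
    CountMatrix,
    GeneAnnotation,
    SequenceSet,
    counts_to_anndata,
)

logger = logging.getLogger("scdeplete")

CATEGORY_ORDER = ("rrna", "mito", "ribo", "nvg")

DEFAULT_N_HVG = 5000
DEFAULT_N_SELECT = 155
DEFAULT_WINDOW_SIZE = 500
DEFAULT_N_SHARED = 100
DEFAULT_N_PER_DATASET = 10
DEFAULT_FLANK = 100


@dataclass
class TargetPanel:
    """Categorised removal targets: gene lists plus genomic intervals."""

    categories: dict[str, list[str]] = field(default_factory=dict)
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cat in CATEGORY_ORDER:
            self.categories.setdefault(cat, [])
            for g in self.categories[cat]:
                if g in seen:
                    raise ValueError(f"gene {g!r} appears in more than one category")
                seen.add(g)

    @property
    def panel_size(self) -> int:
        return len(self.gene_set())

    def gene_set(self) -> set[str]:
        return {g for genes in self.categories.values() for g in genes}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"categories": self.categories, "intervals": [list(iv) for iv in self.intervals]},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TargetPanel":
        data = json.loads(Path(path).read_text())
        return cls(
            categories={k: list(v) for k, v in data["categories"].items()},
            intervals=[tuple(iv) for iv in data["intervals"]],
        )


@dataclass
class CoverageTrack:
    """Read-start counts over fixed windows, one vector per contig."""

    depths: dict[str, np.ndarray]
    window_size: int = DEFAULT_WINDOW_SIZE


def select_nvg(
    datasets: list[CountMatrix],
    n_hvg: int = DEFAULT_N_HVG,
    n_select: int = DEFAULT_N_SELECT,
) -> list[str]:
    """Pick non-variable genes: abundant in every dataset, variable in none.

    Per dataset, counts are normalised per cell to 10,000, log1p
    transformed, and the ``n_hvg`` most variable genes (normalized
    dispersion, mean-binned) are excluded; the remainder is ranked by mean
    normalised expression, descending.  Across datasets a gene's aggregate
    rank is its worst (maximum) per-dataset rank; genes excluded from (or
    absent in) any dataset are dropped.  The ``n_select`` genes with the
    best aggregate ranks are returned, ties broken by gene id.
    """
    import scanpy as sc

    if not datasets:
        raise ValueError("select_nvg requires at least one dataset")

    per_dataset_ranks: list[dict[str, int]] = []
    for m in datasets:
        if n_hvg >= m.n_genes:
            raise ValueError(
                f"n_hvg ({n_hvg}) must be smaller than the gene count ({m.n_genes})"
            )
        adata = counts_to_anndata(m)
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
        keep = ~adata.var["highly_variable"].to_numpy()
        means = np.asarray(adata.X.mean(axis=0)).ravel()
        remainder = [(g, mu) for g, mu, k in zip(m.gene_ids, means, keep) if k]
        # descending mean expression; rank 0 = most abundant
        remainder.sort(key=lambda t: (-t[1], t[0]))
        per_dataset_ranks.append({g: r for r, (g, _) in enumerate(remainder)})

    common = set(per_dataset_ranks[0])
    for ranks in per_dataset_ranks[1:]:
        common &= set(ranks)
    aggregate = sorted(
        ((max(r[g] for r in per_dataset_ranks), g) for g in common),
        key=lambda t: (t[0], t[1]),
    )
    selected = [g for _, g in aggregate[:n_select]]
    logger.info("select_nvg: %d candidate genes, selected %d", len(common), len(selected))
    return selected


def _protein_coding_spans(annotation: GeneAnnotation) -> dict[str, list[tuple[int, int]]]:
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.protein_coding():
        spans.setdefault(g.contig, []).append((g.start, g.end))
    return spans


def _overlaps_any(start: int, end: int, spans: list[tuple[int, int]]) -> bool:
    return any(s < end and e > start for s, e in spans)


def coverage_track(
    read_intervals: list[tuple[str, int, int]],
    annotation: GeneAnnotation,
    contig_lengths: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> CoverageTrack:
    """Bin intergenic read starts into fixed windows for one dataset.

    Reads overlapping any protein-coding gene span (>= 1 bp) are discarded;
    the remainder are counted into the window containing their start.
    """
    if window_size <= 0:
        raise ConfigurationError("window_size must be positive")
    pc = _protein_coding_spans(annotation)
    depths = {
        contig: np.zeros(-(-length // window_size), dtype=np.int64)
        for contig, length in contig_lengths.items()
    }
    for contig, start, end in read_intervals:
        if contig not in depths:
            continue
        if _overlaps_any(start, end, pc.get(contig, [])):
            continue
        depths[contig][start // window_size] += 1
    return CoverageTrack(depths, window_size)


def rank_genomic_intervals(
    read_intervals: list[list[tuple[str, int, int]]],
    annotation: GeneAnnotation,
    contig_lengths: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    n_shared: int = DEFAULT_N_SHARED,
    n_per_dataset: int = DEFAULT_N_PER_DATASET,
) -> list[tuple[str, int, int]]:
    """Rank intergenic windows by coverage: shared first, then dataset-specific.

    Each dataset's intergenic read starts are binned into fixed windows; a
    window's shared score is its minimum depth across datasets.  The top
    ``n_shared`` windows by shared score are selected, followed by the top
    ``n_per_dataset`` windows per dataset not already chosen.  Windows that
    intersect a protein-coding gene span are never returned.
    """
    if window_size <= 0:
        raise ConfigurationError("window_size must be positive")
    tracks = [
        coverage_track(reads, annotation, contig_lengths, window_size)
        for reads in read_intervals
    ]
    pc = _protein_coding_spans(annotation)

    def window_ok(contig: str, w: int) -> bool:
        ws, we = w * window_size, min((w + 1) * window_size, contig_lengths[contig])
        return not _overlaps_any(ws, we, pc.get(contig, []))

    windows = [
        (contig, w)
        for contig, length in contig_lengths.items()
        for w in range(-(-length // window_size))
        if window_ok(contig, w)
    ]

    def depth(track: CoverageTrack, contig: str, w: int) -> int:
        return int(track.depths[contig][w])

    shared = sorted(
        (
            (min(depth(t, c, w) for t in tracks), c, w)
            for c, w in windows
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    chosen: list[tuple[str, int]] = [(c, w) for d, c, w in shared[:n_shared] if d > 0]
    chosen_set = set(chosen)

    for track in tracks:
        specific = sorted(
            ((depth(track, c, w), c, w) for c, w in windows if (c, w) not in chosen_set),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        for d, c, w in specific[:n_per_dataset]:
            if d > 0:
                chosen.append((c, w))
                chosen_set.add((c, w))

    out = sorted(
        {
            (c, w * window_size, min((w + 1) * window_size, contig_lengths[c]))
            for c, w in chosen_set
        }
    )
    logger.info("rank_genomic_intervals: selected %d windows", len(out))
    return out


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping or adjacent intervals per contig."""
    merged: list[tuple[str, int, int]] = []
    for contig, start, end in sorted(intervals):
        if merged and merged[-1][0] == contig and start <= merged[-1][2]:
            merged[-1] = (contig, merged[-1][1], max(merged[-1][2], end))
        else:
            merged.append((contig, start, end))
    return merged


def assemble_panel(
    ribo_genes: list[str],
    mito_genes: list[str],
    nvg_genes: list[str],
    rrna_genes: list[str] = (),
    intervals: list[tuple[str, int, int]] = (),
) -> TargetPanel:
    """Combine the category gene lists and intervals into one panel.

    A gene appearing in more than one list is assigned to the first
    category in precedence order rRNA > mito > ribo > nvg, with a warning.
    Intervals are merged.
    """
    inputs = {"rrna": rrna_genes, "mito": mito_genes, "ribo": ribo_genes, "nvg": nvg_genes}
    categories: dict[str, list[str]] = {c: [] for c in CATEGORY_ORDER}
    seen: set[str] = set()
    for cat in CATEGORY_ORDER:
        for g in inputs[cat]:
            if g in seen:
                logger.warning("gene %s already assigned to an earlier category; skipping", g)
                continue
            categories[cat].append(g)
            seen.add(g)
    if not seen:
        raise ValueError("panel has no genes (gene lists are empty)")
    panel = TargetPanel(categories, merge_intervals(list(intervals)))
    logger.info(
        "assembled panel: %d genes (%s), %d intervals",
        panel.panel_size,
        ", ".join(f"{c}={len(categories[c])}" for c in CATEGORY_ORDER),
        len(panel.intervals),
    )
    return panel


def build_depletion_references(
    panel: TargetPanel,
    genome: SequenceSet,
    annotation: GeneAnnotation,
    flank: int = DEFAULT_FLANK,
) -> dict[str, SequenceSet]:
    """Extract per-category depletion reference sequences from the genome.

    Protein-coding panel genes contribute their unspliced genomic span
    plus ``flank`` bases on each side (clipped at contig ends); rRNA genes
    their exact span; panel intervals their exact sequence.  Returns one
    SequenceSet per category key: 'gene', 'rrna', 'interval'.
    """
    gene_cats = [g for cat in ("mito", "ribo", "nvg") for g in panel.categories[cat]]
    missing = [g for g in gene_cats + panel.categories["rrna"] if g not in annotation]
    if missing:
        raise LookupError(f"panel genes missing from annotation: {sorted(missing)}")

    def span_seq(gene_id: str, pad: int) -> str:
        g = annotation.genes[gene_id]
        contig = genome[g.contig]
        return contig[max(0, g.start - pad) : min(len(contig), g.end + pad)]

    gene_records = {f"gene|{g}": span_seq(g, flank) for g in gene_cats}
    rrna_records = {f"rrna|{g}": span_seq(g, 0) for g in panel.categories["rrna"]}
    interval_records = {
        f"interval|{contig}:{start}-{end}": genome[contig][start:end]
        for contig, start, end in panel.intervals
    }
    return {
        "gene": SequenceSet(gene_records),
        "rrna": SequenceSet(rrna_records),
        "interval": SequenceSet(interval_records),
    }


def build_depletion_reference(
    panel: TargetPanel,
    genome: SequenceSet,
    annotation: GeneAnnotation,
    flank: int = DEFAULT_FLANK,
) -> SequenceSet:
    """All depletion reference records (gene + rRNA + interval) in one set."""
    refs = build_depletion_references(panel, genome, annotation, flank)
    combined: dict[str, str] = {}
    for cat in ("gene", "rrna", "interval"):
        combined.update(refs[cat].records)
    return SequenceSet(combined)
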