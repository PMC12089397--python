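"""Synthetic genomes, annotations, count matrices and barcoded read sets.

The generator plants the structure the toolkit is built to detect: a
block of abundant panel-like genes holding a target share of all UMIs,
housekeeping genes with high mean and low variance, HVG-like genes with
strong extra per-cell variability, rRNA-like records, intergenic hotspot
windows, and diffuse intergenic background reads.  Every read and gene
carries a truth label so downstream recovery checks compare against an
exact reference rather than an estimate.

Default library conditions: 1,000 cells x 2,000 genes at 2,000 UMIs per
cell, with the 100 panel-like genes holding half of all UMIs - the
regime in which depletion doubles the informative transcriptome.  The
default extra-read fractions (10% rRNA carryover, 9% hotspot intervals,
5% diffuse intergenic) echo the read-composition medians reported for
droplet 3' scRNA-seq surveys.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BarcodedReadSet, CountMatrix, GeneAnnotation, GeneRecord, ReadPair, SequenceSet

logger = logging.getLogger("scdeplete")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class LibrarySpec:
    """All knobs of the synthetic library generator."""

    n_cells: int = 1000
    n_genes: int = 2000
    depth: int = 2000  # per-cell UMI total
    depth_cv: float = 0.0  # 0 = every cell exactly `depth`
    abundance_sigma: float = 1.0  # log-normal sigma of base gene abundance
    n_panel_genes: int = 100
    targeted_share: float = 0.5  # UMI share planted into panel-like genes
    n_housekeeping: int = 50
    housekeeping_boost: float = 10.0
    n_hvg_like: int = 100
    hvg_sigma: float = 1.5  # per-cell log-normal noise for HVG-like genes
    # genome layout
    n_contigs: int = 1
    gene_length: int = 600
    spacing: int = 400
    n_rrna: int = 2
    rrna_length: int = 400
    n_hotspots: int = 4
    window_size: int = 500
    background_length: int = 3000
    planted_overlap: bool = False
    # reads
    read_length: int = 91
    barcode_len: int = 16
    umi_len: int = 12
    rrna_read_fraction: float = 0.10
    hotspot_read_fraction: float = 0.09
    background_read_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.targeted_share < 1:
            raise ValueError("targeted_share must be in (0, 1)")
        if self.n_panel_genes + self.n_housekeeping + self.n_hvg_like > self.n_genes:
            raise ValueError("planted gene sets exceed n_genes")
        extra = self.rrna_read_fraction + self.hotspot_read_fraction + self.background_read_fraction
        if extra >= 1:
            raise ValueError("extra read fractions must sum to < 1")

    # planted sets occupy disjoint leading blocks of the gene namespace
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def panel_gene_ids(self) -> list[str]:
        return self.gene_ids()[: self.n_panel_genes]

    def housekeeping_ids(self) -> list[str]:
        return self.gene_ids()[self.n_panel_genes : self.n_panel_genes + self.n_housekeeping]

    def hvg_ids(self) -> list[str]:
        lo = self.n_panel_genes + self.n_housekeeping
        return self.gene_ids()[lo : lo + self.n_hvg_like]

    def rrna_ids(self) -> list[str]:
        return [f"RRNA{i}" for i in range(self.n_rrna)]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _contig_of(spec: LibrarySpec, gene_index: int) -> tuple[str, int]:
    """(contig name, per-contig slot) for the i-th gene."""
    return f"chr{gene_index % spec.n_contigs + 1}", gene_index // spec.n_contigs


def _layout(spec: LibrarySpec) -> dict[str, object]:
    """Deterministic genome layout (independent of the seed).

    Per contig: alternating [spacing][gene] blocks for its share of genes,
    rRNA genes (contig 1 only), window-aligned hotspot slots, then a
    diffuse intergenic background stretch.
    """
    gene_spans: dict[str, tuple[str, int, int]] = {}
    gene_ids = spec.gene_ids()
    per_contig_end = {f"chr{c + 1}": 0 for c in range(spec.n_contigs)}
    for i, gid in enumerate(gene_ids):
        contig, slot = _contig_of(spec, i)
        start = (slot + 1) * spec.spacing + slot * spec.gene_length
        end = start + spec.gene_length
        gene_spans[gid] = (contig, start, end)
        per_contig_end[contig] = max(per_contig_end[contig], end + spec.spacing)

    rrna_spans: dict[str, tuple[str, int, int]] = {}
    pos = per_contig_end["chr1"]
    for rid in spec.rrna_ids():
        rrna_spans[rid] = ("chr1", pos, pos + spec.rrna_length)
        pos += spec.rrna_length + spec.spacing
    per_contig_end["chr1"] = pos

    w = spec.window_size
    hs_base = math.ceil(per_contig_end["chr1"] / w) * w
    hotspots = [("chr1", hs_base + 2 * k * w, hs_base + 2 * k * w + w) for k in range(spec.n_hotspots)]
    if hotspots:
        per_contig_end["chr1"] = hotspots[-1][2] + w

    background: dict[str, tuple[int, int]] = {}
    contig_lengths: dict[str, int] = {}
    for contig, end in per_contig_end.items():
        bg_start = end + spec.spacing
        background[contig] = (bg_start, bg_start + spec.background_length)
        contig_lengths[contig] = bg_start + spec.background_length + spec.spacing

    if spec.planted_overlap:
        contig, s, e = gene_spans[gene_ids[0]]
        gene_spans["G_OVLP"] = (contig, s + 50, e - 50)

    return {
        "gene_spans": gene_spans,
        "rrna_spans": rrna_spans,
        "hotspots": hotspots,
        "background": background,
        "contig_lengths": contig_lengths,
    }


def hotspot_windows(spec: LibrarySpec) -> list[tuple[str, int, int]]:
    """The planted intergenic hotspot windows (window-aligned)."""
    return list(_layout(spec)["hotspots"])


def contig_lengths(spec: LibrarySpec) -> dict[str, int]:
    return dict(_layout(spec)["contig_lengths"])


def make_genome(spec: LibrarySpec, seed: int = 0) -> tuple[SequenceSet, GeneAnnotation]:
    """Random contigs with non-overlapping genes, rRNA records and hotspots.

    Gene/hotspot placement is a deterministic function of the spec; the
    sequence content is a pure function of the seed.
    """
    layout = _layout(spec)
    lengths: dict[str, int] = layout["contig_lengths"]
    rng = np.random.default_rng(seed)
    seqs = SequenceSet({contig: _random_seq(rng, n) for contig, n in sorted(lengths.items())})

    genes: dict[str, GeneRecord] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for gid, (contig, s, e) in layout["gene_spans"].items():
        if e > lengths[contig]:
            raise ValueError("requested features exceed contig capacity")
        genes[gid] = GeneRecord(gid, contig, s, e, "+", "protein_coding")
        third = (e - s) // 3
        exons[gid] = [(s, s + third), (e - third, e)]
    for rid, (contig, s, e) in layout["rrna_spans"].items():
        genes[rid] = GeneRecord(rid, contig, s, e, "+", "rRNA")
        exons[rid] = [(s, e)]
    return seqs, GeneAnnotation(genes, exons)


def _abundance(spec: LibrarySpec, rng: np.random.Generator) -> np.ndarray:
    """Base per-gene abundance with the planted panel share."""
    a = rng.lognormal(0.0, spec.abundance_sigma, size=spec.n_genes)
    hk = slice(spec.n_panel_genes, spec.n_panel_genes + spec.n_housekeeping)
    a[hk] *= spec.housekeeping_boost
    panel = slice(0, spec.n_panel_genes)
    rest = slice(spec.n_panel_genes, spec.n_genes)
    if spec.n_panel_genes and spec.n_panel_genes < spec.n_genes:
        a[panel] *= spec.targeted_share / a[panel].sum()
        a[rest] *= (1 - spec.targeted_share) / a[rest].sum()
    else:
        a /= a.sum()
    return a


def simulate_counts(spec: LibrarySpec, seed: int = 0) -> CountMatrix:
    """Draw a gene x cell UMI matrix with the planted abundance structure.

    Per-cell totals follow the depth distribution (degenerate at
    ``spec.depth`` when depth_cv = 0); per-cell gene draws are multinomial
    over the cell-specific abundance, in which the panel-like genes hold
    an expected share ``targeted_share`` and HVG-like genes carry extra
    log-normal per-cell noise.
    """
    rng = np.random.default_rng(seed)
    base = _abundance(spec, rng)
    if spec.depth_cv > 0:
        sigma = math.sqrt(math.log(1 + spec.depth_cv**2))
        totals = np.maximum(
            1, rng.lognormal(math.log(spec.depth) - sigma**2 / 2, sigma, spec.n_cells)
        ).astype(int)
    else:
        totals = np.full(spec.n_cells, spec.depth, dtype=int)

    barcodes = _distinct_barcodes(spec.n_cells, spec.barcode_len, rng)
    hvg = slice(
        spec.n_panel_genes + spec.n_housekeeping,
        spec.n_panel_genes + spec.n_housekeeping + spec.n_hvg_like,
    )
    counts = np.empty((spec.n_genes, spec.n_cells), dtype=np.int64)
    if spec.n_hvg_like == 0:
        p = base / base.sum()
        counts[:] = rng.multinomial(spec.depth, p, size=spec.n_cells).T if spec.depth_cv == 0 else 0
        if spec.depth_cv > 0:
            for c in range(spec.n_cells):
                counts[:, c] = rng.multinomial(totals[c], p)
    else:
        for c in range(spec.n_cells):
            rates = base.copy()
            # mean-one multiplicative noise so planted shares stay unbiased
            rates[hvg] *= rng.lognormal(-spec.hvg_sigma**2 / 2, spec.hvg_sigma, spec.n_hvg_like)
            counts[:, c] = rng.multinomial(totals[c], rates / rates.sum())
    return CountMatrix(counts, spec.gene_ids(), barcodes)


def _distinct_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        out.add(_random_seq(rng, length))
    return sorted(out)[:n]


def simulate_reads(
    matrix: CountMatrix,
    genome: SequenceSet,
    annotation: GeneAnnotation,
    spec: LibrarySpec,
    seed: int = 0,
) -> tuple[BarcodedReadSet, pd.DataFrame]:
    """One read pair per UMI plus planted rRNA/hotspot/background reads.

    R1 carries the cell barcode + a fresh UMI; R2 is a substring of the
    gene's unspliced genomic sequence at a random offset.  Extra reads
    are drawn from rRNA-like records, hotspot windows and diffuse
    intergenic background to realise the spec's bucket fractions.  Truth
    labels (category and source gene) are returned for every read.
    """
    rng = np.random.default_rng(seed)
    layout = _layout(spec)
    rl = spec.read_length

    def substring(contig: str, s: int, e: int) -> str:
        if e - s <= rl:
            logger.warning("feature %s:%d-%d shorter than read length; clamped", contig, s, e)
            return genome[contig][s:e]
        off = int(rng.integers(s, e - rl + 1))
        return genome[contig][off : off + rl]

    missing = [g for g in matrix.gene_ids if g not in annotation]
    if missing:
        raise ValueError(f"matrix genes missing from annotation: {missing[:5]}")

    n_tx = int(matrix.counts.sum())
    extra_f = spec.rrna_read_fraction + spec.hotspot_read_fraction + spec.background_read_fraction
    total = int(round(n_tx / (1 - extra_f))) if extra_f > 0 else n_tx
    n_rrna = int(round(total * spec.rrna_read_fraction))
    n_hot = int(round(total * spec.hotspot_read_fraction))
    n_bg = int(round(total * spec.background_read_fraction))

    pairs: list[ReadPair] = []
    truth_rows: list[tuple[str, str, str | None, str]] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"R{counter:08d}"

    gene_idx, cell_idx = np.nonzero(matrix.counts)
    for gi, ci in zip(gene_idx, cell_idx):
        g = annotation.genes[matrix.gene_ids[gi]]
        bc = matrix.cell_barcodes[ci]
        for _ in range(int(matrix.counts[gi, ci])):
            rid = next_id()
            pairs.append(
                ReadPair(rid, bc, _random_seq(rng, spec.umi_len), substring(g.contig, g.start, g.end))
            )
            truth_rows.append((rid, "gene", g.gene_id, bc))

    rrna_spans = list(layout["rrna_spans"].items())
    for _ in range(n_rrna):
        rid_name, (contig, s, e) = rrna_spans[int(rng.integers(len(rrna_spans)))]
        bc = matrix.cell_barcodes[int(rng.integers(matrix.n_cells))]
        rid = next_id()
        pairs.append(ReadPair(rid, bc, _random_seq(rng, spec.umi_len), substring(contig, s, e)))
        truth_rows.append((rid, "rrna", rid_name, bc))

    hotspots = layout["hotspots"]
    for _ in range(n_hot):
        contig, s, e = hotspots[int(rng.integers(len(hotspots)))]
        bc = matrix.cell_barcodes[int(rng.integers(matrix.n_cells))]
        rid = next_id()
        pairs.append(ReadPair(rid, bc, _random_seq(rng, spec.umi_len), substring(contig, s, e)))
        truth_rows.append((rid, "hotspot", None, bc))

    background = layout["background"]
    bg_contigs = sorted(background)
    for _ in range(n_bg):
        contig = bg_contigs[int(rng.integers(len(bg_contigs)))]
        s, e = background[contig]
        bc = matrix.cell_barcodes[int(rng.integers(matrix.n_cells))]
        rid = next_id()
        pairs.append(ReadPair(rid, bc, _random_seq(rng, spec.umi_len), substring(contig, s, e)))
        truth_rows.append((rid, "intergenic", None, bc))

    reads = BarcodedReadSet(pairs, spec.barcode_len, spec.umi_len)
    truth = pd.DataFrame(truth_rows, columns=["read_id", "category", "gene_id", "barcode"])
    return reads, truth


def counts_from_reads(
    reads: BarcodedReadSet,
    truth: pd.DataFrame,
    gene_ids: list[str],
    cell_barcodes: list[str],
) -> CountMatrix:
    """Rebuild a gene x cell matrix from reads using the truth gene labels.

    Each read pair is one UMI; only transcriptomic ('gene' category) reads
    with a gene in ``gene_ids`` contribute.
    """
    keep = set(p.read_id for p in reads)
    gmap = {g: i for i, g in enumerate(gene_ids)}
    cmap = {b: i for i, b in enumerate(cell_barcodes)}
    counts = np.zeros((len(gene_ids), len(cell_barcodes)), dtype=np.int64)
    sub = truth[truth["category"] == "gene"]
    for rid, gid, bc in zip(sub["read_id"], sub["gene_id"], sub["barcode"]):
        if rid in keep and gid in gmap and bc in cmap:
            counts[gmap[gid], cmap[bc]] += 1
    return CountMatrix(counts, list(gene_ids), list(cell_barcodes))


def truth_read_gene(truth: pd.DataFrame) -> dict[str, str | None]:
    """read id -> source gene (None for intergenic/hotspot reads)."""
    out: dict[str, str | None] = {}
    for rid, cat, gid in zip(truth["read_id"], truth["category"], truth["gene_id"]):
        out[rid] = gid if cat in ("gene", "rrna") else None
    return out
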