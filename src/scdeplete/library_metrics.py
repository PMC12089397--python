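"""Library recomposition metrics.

Quantifies what depletion does to a library: how aligned reads split
into genomic / targeted / informative buckets, how concentrated UMIs are
in the most abundant genes, per-cell complexity (unique genes per UMI),
and how many principal components rise above the Marchenko-Pastur noise
edge of a random matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .insilico_depletion import RETAINED, ReadClassification
from .io_formats import CountMatrix

logger = logging.getLogger("scdeplete")

DEFAULT_TOP_N = (50, 100, 200, 500)


@dataclass
class BucketFractions:
    """Percentages of aligned reads: intergenic, depletion-targeted, informative."""

    genomic: float
    targeted: float
    informative: float

    def __post_init__(self) -> None:
        total = self.genomic + self.targeted + self.informative
        if min(self.genomic, self.targeted, self.informative) < 0 or abs(total - 100) > 1e-6:
            raise ValueError(f"bucket percentages must be >= 0 and sum to 100 (got {total})")


@dataclass
class ComplexityProfile:
    """Per-cell genes detected and total UMIs, with median-based summaries."""

    genes_detected: np.ndarray
    total_umis: np.ndarray
    complexity_ratio: float
    genes_per_1000_umis: np.ndarray
    median_genes_per_1000_umis: float


@dataclass
class MPModel:
    """Marchenko-Pastur noise model of a standardized expression matrix."""

    n_cells: int
    n_genes: int
    gamma: float
    mp_upper_edge: float
    n_signal_components: int
    eigenvalues: np.ndarray = field(repr=False, default=None)


def bucket_fractions(
    classification: ReadClassification,
    read_gene: dict[str, str | None],
    panel_genes: set[str] | None = None,
) -> BucketFractions:
    """Split reads into genomic / targeted / informative buckets.

    ``read_gene`` maps every read id to the transcript (gene id) it derives
    from, or None for intergenic reads - truth labels from the synthetic
    generator or an externally produced read->gene table.  Targeted =
    reads the classifier labelled as any targeted category; informative =
    retained reads assigned to a (non-panel) transcript; genomic =
    retained reads with no transcript assignment.
    """
    missing = [rid for rid in classification.labels if rid not in read_gene]
    if missing:
        raise ValueError(f"reads without a transcript assignment: {missing[:5]}...")
    n = len(classification.labels)
    if n == 0:
        raise ValueError("empty classification")
    targeted = genomic = informative = 0
    for rid, label in classification.labels.items():
        if label != RETAINED:
            targeted += 1
        elif read_gene[rid] is None:
            genomic += 1
        elif panel_genes is not None and read_gene[rid] in panel_genes:
            # retained despite deriving from a panel transcript: still counted
            # as targeted material for composition purposes
            targeted += 1
        else:
            informative += 1
    return BucketFractions(100 * genomic / n, 100 * targeted / n, 100 * informative / n)


def top_n_umi_fraction(
    matrix: CountMatrix,
    n_list: tuple[int, ...] = DEFAULT_TOP_N,
    per_cell_ranking: bool = False,
) -> dict[int, dict[str, object]]:
    """Fraction of each cell's UMIs held by the top-N most abundant genes.

    By default genes are ranked once, library-wide, by total UMIs across
    all cells; ``per_cell_ranking=True`` instead ranks genes within each
    cell.  Returns per-N the per-cell fraction vector and its median.
    """
    totals = matrix.counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("every cell must have > 0 UMIs")
    out: dict[int, dict[str, object]] = {}
    order = np.argsort(-matrix.counts.sum(axis=1), kind="stable")
    for n in n_list:
        if n > matrix.n_genes:
            logger.warning("top-N %d exceeds gene count %d; clamping", n, matrix.n_genes)
            n_eff = matrix.n_genes
        else:
            n_eff = n
        if per_cell_ranking:
            sorted_counts = -np.sort(-matrix.counts, axis=0)
            fracs = sorted_counts[:n_eff, :].sum(axis=0) / totals
        else:
            fracs = matrix.counts[order[:n_eff], :].sum(axis=0) / totals
        out[n] = {"fractions": fracs, "median": float(np.median(fracs))}
    return out


def complexity_profile(matrix: CountMatrix) -> ComplexityProfile:
    """Per-cell unique genes vs UMIs, and the median-genes / median-UMIs ratio."""
    totals = matrix.counts.sum(axis=0)
    if totals.sum() == 0:
        raise ValueError("matrix has no counts")
    genes = (matrix.counts > 0).sum(axis=0)
    per_1000 = 1000.0 * genes / np.maximum(totals, 1)
    return ComplexityProfile(
        genes_detected=genes,
        total_umis=totals,
        complexity_ratio=float(np.median(genes) / np.median(totals)),
        genes_per_1000_umis=per_1000,
        median_genes_per_1000_umis=float(np.median(per_1000)),
    )


def mp_signal_components(standardized: np.ndarray) -> MPModel:
    """Count eigenvalues above the Marchenko-Pastur edge of a cells x genes matrix.

    ``standardized`` must have genes with mean 0 and variance 1 across
    cells; for unit-variance i.i.d. entries the largest noise eigenvalue
    of the gene-gene correlation matrix converges to
    lambda+ = (1 + sqrt(gamma))^2 with gamma = n_genes / n_cells.
    """
    n_cells, n_genes = standardized.shape
    if n_cells < 2 or n_genes < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    gamma = n_genes / n_cells
    lam_plus = (1 + np.sqrt(gamma)) ** 2
    # eigenvalues of (1/n_cells) X^T X via singular values of X
    svals = np.linalg.svd(standardized, compute_uv=False)
    eigs = svals**2 / n_cells
    return MPModel(
        n_cells=n_cells,
        n_genes=n_genes,
        gamma=gamma,
        mp_upper_edge=float(lam_plus),
        n_signal_components=int(np.sum(eigs > lam_plus)),
        eigenvalues=eigs,
    )


def signal_components(matrix: CountMatrix) -> MPModel:
    """Random-matrix estimate of the number of signal components in a library.

    Counts are normalised per cell to 10,000, log1p transformed, and each
    gene standardized to mean 0 / variance 1 (zero-variance genes
    dropped); eigenvalues of the gene-gene correlation exceeding the
    Marchenko-Pastur edge are counted as signal.
    """
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells")
    totals = matrix.counts.sum(axis=0).astype(np.float64)
    if np.any(totals == 0):
        raise ValueError("every cell must have > 0 UMIs")
    X = np.log1p(1e4 * matrix.counts.T / totals[:, None])
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes with non-zero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return mp_signal_components(Z)
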