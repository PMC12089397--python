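"""Per-tissue / per-cell-type cost-benefit scoring of a depletion panel.

Answers "is this panel safe for my sample?": tau tissue specificity of
each gene, the fraction of a tissue's expression the panel would remove,
where panel genes fall in a variance (or mean) binning, preranked
gene-set enrichment of the panel against a ranked gene list, and overlap
with curated cell-type marker tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ConfigurationError
from .target_selection import TargetPanel

logger = logging.getLogger("scdeplete")

DEFAULT_TAU_FLOOR = 1.0  # TPM
DEFAULT_TAU_THRESHOLD = 0.8
DEFAULT_N_BINS = 7
DEFAULT_N_PERM = 1000
DEFAULT_WEIGHT_EXPONENT = 1.0


@dataclass
class TauProfile:
    """Per-gene tau tissue-specificity scores (0 uniform .. 1 single-tissue)."""

    tau: pd.Series  # NaN where max expression fell below the floor
    flagged_specific: list[str]
    floor: float
    threshold: float


@dataclass
class EnrichmentResult:
    """Preranked weighted-KS enrichment of one gene set."""

    es: float
    nes: float
    p_value: float
    fdr: float
    n_permutations: int
    seed: int
    running_sum: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not -1 <= self.es <= 1:
            raise ValueError("ES must lie in [-1, 1]")


@dataclass
class BinReport:
    """Equal-interval binning of a per-gene statistic with panel proportions."""

    edges: np.ndarray
    panel_proportion: np.ndarray  # fraction of genes in each bin that are panel members
    n_genes: np.ndarray
    n_panel: np.ndarray


def tau_specificity(
    expr: pd.DataFrame,
    floor: float = DEFAULT_TAU_FLOOR,
    log_base: float = 2.0,
    threshold: float = DEFAULT_TAU_THRESHOLD,
) -> TauProfile:
    """Tau tissue specificity on a gene x tissue expression table.

    Expression is log(x+1)-transformed (base ``log_base``); genes whose
    maximum raw expression across tissues is below ``floor`` are reported
    as missing.  tau = sum_i (1 - x_i/max) / (n-1) over n tissues; 0 for
    uniform expression, 1 for single-tissue expression.
    """
    if expr.shape[1] < 2:
        raise ValueError("tau requires at least 2 tissues")
    values = expr.to_numpy(dtype=float)
    logged = np.log1p(values) / np.log(log_base)
    maxima = logged.max(axis=1)
    raw_max = values.max(axis=1)
    n = expr.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = logged / maxima[:, None]
        tau = (1 - xhat).sum(axis=1) / (n - 1)
    tau = np.where(raw_max < floor, np.nan, tau)
    series = pd.Series(tau, index=expr.index, name="tau")
    flagged = series.index[(series >= threshold).fillna(False)].tolist()
    return TauProfile(series, flagged, floor, threshold)


def panel_expression_fraction(expr: pd.DataFrame, panel: TargetPanel) -> pd.Series:
    """Per-group fraction of total expression contributed by panel genes.

    Panel genes absent from the table count as zero (with a warning);
    groups with zero total expression are reported as missing.
    """
    genes = panel.gene_set()
    absent = genes - set(expr.index)
    if absent:
        logger.warning("%d panel genes absent from expression table", len(absent))
    present = sorted(genes & set(expr.index))
    totals = expr.sum(axis=0)
    panel_totals = expr.loc[present].sum(axis=0) if present else pd.Series(0.0, index=expr.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = panel_totals / totals
    return frac.where(totals > 0, np.nan).rename("panel_fraction")


def bin_genes(
    statistic: pd.Series,
    panel: TargetPanel | set[str],
    n_bins: int = DEFAULT_N_BINS,
) -> BinReport:
    """Equal-interval binning of a per-gene statistic, reporting panel share.

    Bin edges span [min, max] of the statistic in ``n_bins`` equal
    intervals; each bin's value is the proportion of its genes that are
    panel members.  Bins are right-open except the last; edge ties go to
    the lower bin.
    """
    panel_genes = panel.gene_set() if isinstance(panel, TargetPanel) else set(panel)
    values = statistic.to_numpy(dtype=float)
    if len(np.unique(values)) < n_bins:
        raise ValueError(f"need at least {n_bins} distinct values for {n_bins} bins")
    edges = np.linspace(values.min(), values.max(), n_bins + 1)
    # np.digitize(right=True) puts edge ties in the lower bin
    idx = np.clip(np.digitize(values, edges[1:], right=True), 0, n_bins - 1)
    is_panel = statistic.index.isin(panel_genes)
    n_genes = np.bincount(idx, minlength=n_bins)
    n_panel = np.bincount(idx, weights=is_panel.astype(float), minlength=n_bins).astype(int)
    with np.errstate(invalid="ignore"):
        prop = np.where(n_genes > 0, n_panel / np.maximum(n_genes, 1), 0.0)
    return BinReport(edges, prop, n_genes, n_panel)


def _running_es(
    in_set: np.ndarray, weights: np.ndarray, weight_exponent: float
) -> tuple[float, np.ndarray]:
    w = np.abs(weights) ** weight_exponent
    hit_w = np.where(in_set, w, 0.0)
    hit_total = hit_w.sum()
    n_miss = int((~in_set).sum())
    if hit_total == 0 or n_miss == 0:
        return 0.0, np.zeros(len(in_set))
    steps = hit_w / hit_total - np.where(in_set, 0.0, 1.0 / n_miss)
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(np.clip(es, -1.0, 1.0)), running


def preranked_enrichment(
    ranked_genes: list[str],
    panel: TargetPanel | set[str],
    statistic: np.ndarray | None = None,
    n_perm: int = DEFAULT_N_PERM,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted Kolmogorov-Smirnov preranked enrichment of the panel.

    ``ranked_genes`` is ordered by descending statistic (most variable /
    abundant first); ``statistic`` supplies the per-gene ranking values
    used as hit weights (|statistic|^exponent), defaulting to a linear
    N..1 surrogate.  The null is built from random same-size gene sets;
    NES = ES / mean(|null ES| of the same sign); the two-sided p-value is
    the null exceedance frequency, and FDR for this single set equals p.
    """
    panel_genes = panel.gene_set() if isinstance(panel, TargetPanel) else set(panel)
    n = len(ranked_genes)
    in_set = np.array([g in panel_genes for g in ranked_genes])
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("panel has no overlap with the ranked gene list")
    weights = (
        np.asarray(statistic, dtype=float)
        if statistic is not None
        else np.linspace(n, 1, n)
    )
    es, running = _running_es(in_set, weights, weight_exponent)

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        null_es[i], _ = _running_es(perm, weights, weight_exponent)

    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    denom = np.mean(np.abs(same_sign)) if len(same_sign) else np.mean(np.abs(null_es))
    nes = es / denom if denom > 0 else 0.0
    p = float((np.sum(np.abs(null_es) >= abs(es)) + 1) / (n_perm + 1))
    return EnrichmentResult(es, float(nes), p, p, n_perm, seed, running)


def marker_overlap_report(
    marker_table: dict[str, list[str]],
    panel: TargetPanel | set[str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Overlap of panel genes with cell-type marker lists.

    Returns a per-cell-type table (n_markers, n_in_panel, pct_retained)
    and a global summary: how many cell types carry at least one panel
    marker, and what fraction of all cell types that is.
    """
    panel_genes = panel.gene_set() if isinstance(panel, TargetPanel) else set(panel)
    if not marker_table:
        raise ValueError("marker table is empty")
    rows = []
    for cell_type, markers in marker_table.items():
        if not markers:
            logger.warning("cell type %s has no markers; skipped", cell_type)
            continue
        n_in = sum(1 for m in markers if m in panel_genes)
        rows.append(
            {
                "cell_type": cell_type,
                "n_markers": len(markers),
                "n_in_panel": n_in,
                "pct_retained": 100.0 * (1 - n_in / len(markers)),
            }
        )
    table = pd.DataFrame(rows).set_index("cell_type")
    affected = int((table["n_in_panel"] > 0).sum())
    summary = {
        "n_cell_types": int(len(table)),
        "n_affected": affected,
        "pct_affected": 100.0 * affected / len(table),
    }
    return table, summary
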