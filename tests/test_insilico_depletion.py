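"""Read- and count-level depletion: classification, removal, re-allocation."""

import numpy as np
import pytest

import scdeplete as sd
from scdeplete.insilico_depletion import RETAINED


@pytest.fixture(scope="module")
def classified(small_library, small_panel):
    refs = sd.build_depletion_references(
        small_panel, small_library["genome"], small_library["annotation"]
    )
    classification = sd.classify_reads(small_library["reads"], refs)
    return refs, classification


# --- classification ------------------------------------------------------


def test_exact_substring_of_panel_gene_is_targeted(classified, small_library, small_panel):
    refs, _ = classified
    ref_seq = refs["gene"][f"gene|{small_panel.categories['nvg'][0]}"]
    read = sd.ReadPair("x1", "A" * 16, "C" * 12, ref_seq[100:190])
    reads = sd.BarcodedReadSet([read], 16, 12)
    cl = sd.classify_reads(reads, refs)
    assert cl.labels["x1"] == "targeted_gene"


def test_random_read_is_retained(classified):
    refs, _ = classified
    rng = np.random.default_rng(0)
    read = sd.ReadPair("x1", "A" * 16, "C" * 12, "".join(rng.choice(list("ACGT"), 90)))
    cl = sd.classify_reads(sd.BarcodedReadSet([read], 16, 12), refs)
    assert cl.labels["x1"] == RETAINED


def test_short_read_is_a_parameter_error(classified):
    refs, _ = classified
    read = sd.ReadPair("x1", "A" * 16, "C" * 12, "ACGTACGT")
    with pytest.raises(sd.io_formats.ConfigurationError):
        sd.classify_reads(sd.BarcodedReadSet([read], 16, 12), refs, k=21)


def test_generative_targeted_fraction_recovered_within_two_points():
    """A library built with 40% panel-gene reads classifies ~40% targeted."""
    spec = sd.LibrarySpec(
        n_cells=40, n_genes=150, depth=120, n_panel_genes=15, targeted_share=0.4,
        n_housekeeping=0, n_hvg_like=0,
        rrna_read_fraction=0.0, hotspot_read_fraction=0.0, background_read_fraction=0.0,
    )
    genome, ann = sd.make_genome(spec, seed=9)
    matrix = sd.simulate_counts(spec, seed=9)
    reads, _ = sd.simulate_reads(matrix, genome, ann, spec, seed=9)
    panel = sd.assemble_panel([], [], spec.panel_gene_ids())
    refs = sd.build_depletion_references(panel, genome, ann)
    cl = sd.classify_reads(reads, refs)
    pct = 100 * cl.n_targeted() / len(reads)
    assert abs(pct - 40) <= 2


# --- read removal and downsampling ---------------------------------------


def test_deplete_reads_bookkeeping(small_library, classified):
    _, classification = classified
    reads = small_library["reads"]
    kept = sd.deplete_reads(reads, classification)
    n_retained = sum(1 for v in classification.labels.values() if v == RETAINED)
    assert len(kept) == n_retained
    assert [p.read_id for p in kept] == [
        p.read_id for p in reads if classification.labels[p.read_id] == RETAINED
    ]


def test_deplete_reads_all_or_nothing(small_library):
    reads = sd.BarcodedReadSet(small_library["reads"].pairs[:10], 16, 12)
    all_t = sd.ReadClassification({p.read_id: "targeted_gene" for p in reads})
    none_t = sd.ReadClassification({p.read_id: RETAINED for p in reads})
    assert len(sd.deplete_reads(reads, all_t)) == 0
    assert [p.read_id for p in sd.deplete_reads(reads, none_t)] == [p.read_id for p in reads]


def test_downsample_edge_cases(small_library):
    reads = sd.BarcodedReadSet(small_library["reads"].pairs[:100], 16, 12)
    assert sorted(p.read_id for p in sd.downsample_pairs(reads, 100, 1)) == sorted(
        p.read_id for p in reads
    )
    assert len(sd.downsample_pairs(reads, 0, 1)) == 0
    with pytest.raises(ValueError):
        sd.downsample_pairs(reads, 101, 1)
    a = [p.read_id for p in sd.downsample_pairs(reads, 10, 7)]
    assert a == [p.read_id for p in sd.downsample_pairs(reads, 10, 7)]  # reproducible


def test_downsample_inclusion_frequency_is_uniform():
    """Per-read inclusion across many seeds matches the binomial expectation."""
    n_reads, n, n_seeds = 2000, 200, 300
    pairs = [sd.ReadPair(f"r{i}", "A" * 16, "C" * 12, "ACGT" * 25) for i in range(n_reads)]
    reads = sd.BarcodedReadSet(pairs, 16, 12)
    freq = np.zeros(n_reads)
    index = {p.read_id: i for i, p in enumerate(pairs)}
    for seed in range(n_seeds):
        for p in sd.downsample_pairs(reads, n, seed):
            freq[index[p.read_id]] += 1
    p0 = n / n_reads
    se = np.sqrt(p0 * (1 - p0) / n_seeds)
    assert np.all(np.abs(freq / n_seeds - p0) < 5.5 * se)


# --- count-level depletion -----------------------------------------------


def test_inert_panel_preserves_counts_in_expectation():
    """A panel with no matrix genes leaves expected counts unchanged."""
    rng = np.random.default_rng(0)
    counts = rng.poisson(4, size=(15, 10)).astype(np.int64)
    counts[0, :] += 1
    m = sd.CountMatrix(counts, [f"g{i}" for i in range(15)], [f"c{i}" for i in range(10)])
    panel = sd.TargetPanel(categories={"nvg": ["absent_gene"]})
    acc = np.zeros_like(counts, dtype=float)
    n_rep = 200
    for seed in range(n_rep):
        depleted, _ = sd.deplete_counts(m, panel, "match", seed)
        acc += depleted.counts
    mean = acc / n_rep
    # multinomial resampling: SE per entry ~ sqrt(n p (1-p)) / sqrt(reps)
    totals = counts.sum(axis=0)
    p = counts / totals
    se = np.sqrt(np.maximum(totals * p * (1 - p), 1e-12) / n_rep)
    z = np.abs(mean - counts) / (se + 1e-12)
    # family-wise bound across all entries; mean |z| must also be ~1
    assert z.max() < 4.5 and z.mean() < 1.5


def test_cell_fully_targeted_is_dropped(caplog):
    counts = np.array([[5, 5], [0, 3]])
    m = sd.CountMatrix(counts, ["gA", "gB"], ["c1", "c2"])
    panel = sd.TargetPanel(categories={"nvg": ["gA"]})
    depleted, summary = sd.deplete_counts(m, panel, "match", 0)
    assert depleted.cell_barcodes == ["c2"]
    assert summary.cells_dropped == 1


def test_half_targeted_share_doubles_informative_reads(small_spec, small_panel):
    """Mean informative fold change over 20 seeds is within 5% of 2 at f = 0.5."""
    folds = []
    for seed in range(20):
        m = sd.simulate_counts(small_spec, seed)
        _, summary = sd.deplete_counts(m, small_panel, "match", seed)
        folds.append(summary.informative_fold_change)
    assert abs(np.mean(folds) - 2.0) <= 0.1


@pytest.mark.parametrize("f", [0.25, 0.5, 0.58])
def test_fold_change_matches_closed_form(f):
    """Expected informative fold change is 1/(1-f) for targeted share f."""
    spec = sd.LibrarySpec(
        n_cells=100, n_genes=300, depth=500, n_panel_genes=30, targeted_share=f,
        n_housekeeping=10, n_hvg_like=20,
    )
    panel = sd.assemble_panel([], [], spec.panel_gene_ids())
    folds = []
    for seed in range(20):
        m = sd.simulate_counts(spec, seed)
        _, summary = sd.deplete_counts(m, panel, "match", seed)
        folds.append(summary.informative_fold_change)
    folds = np.array(folds)
    se = folds.std(ddof=1) / np.sqrt(len(folds))
    assert abs(folds.mean() - 1 / (1 - f)) <= max(3 * se, 0.02)


@pytest.mark.parametrize("seed", range(5))
def test_conservation_and_zeroing_invariants(small_spec, small_panel, seed):
    """Matched-depth depletion preserves per-cell totals; panel rows are zero."""
    m = sd.simulate_counts(small_spec, seed)
    depleted, _ = sd.deplete_counts(m, small_panel, "match", seed)
    surviving = [m.cell_barcodes.index(b) for b in depleted.cell_barcodes]
    assert np.array_equal(depleted.counts.sum(axis=0), m.counts.sum(axis=0)[surviving])
    assert depleted.counts[depleted.gene_index(small_panel.gene_set()), :].sum() == 0


def test_bad_depth_is_a_parameter_error(small_spec, small_panel):
    m = sd.simulate_counts(small_spec, 0)
    with pytest.raises(sd.io_formats.ConfigurationError):
        sd.deplete_counts(m, small_panel, 0, 0)


# --- summaries -----------------------------------------------------------


def test_summary_no_removal_is_identity(small_library):
    reads = sd.BarcodedReadSet(small_library["reads"].pairs[:20], 16, 12)
    cl = sd.ReadClassification({p.read_id: RETAINED for p in reads})
    s = sd.summarize_depletion(reads, sd.deplete_reads(reads, cl), cl)
    assert s.fraction_removed == 0 and s.informative_fold_change == 1


def test_summary_fold_change_closed_form_at_matched_depth(small_library, classified):
    _, cl = classified
    reads = small_library["reads"]
    s = sd.summarize_depletion(reads, sd.deplete_reads(reads, cl), cl)
    assert s.informative_fold_change == pytest.approx(1 / (1 - s.fraction_removed))
    assert sum(s.category_fractions.values()) == pytest.approx(s.fraction_removed)


def test_read_and_count_pipelines_agree(small_library, small_panel):
    """Count matrices built from reads before/after depletion match count-level results."""
    spec = small_library["spec"]
    reads, truth = small_library["reads"], small_library["truth"]
    matrix = small_library["matrix"]
    refs = sd.build_depletion_references(
        small_panel, small_library["genome"], small_library["annotation"]
    )
    cl = sd.classify_reads(reads, refs)
    kept = sd.deplete_reads(reads, cl)
    before = sd.counts_from_reads(reads, truth, matrix.gene_ids, matrix.cell_barcodes)
    after = sd.counts_from_reads(kept, truth, matrix.gene_ids, matrix.cell_barcodes)
    # read-level removal of panel-gene molecules must zero the same rows
    panel_idx = before.gene_index(small_panel.gene_set())
    assert after.counts[panel_idx, :].sum() == 0
    read_frac = 1 - after.counts.sum() / before.counts.sum()
    _, count_summary = sd.deplete_counts(matrix, small_panel, "match", 0)
    assert abs(read_frac - count_summary.fraction_removed) <= 0.02
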