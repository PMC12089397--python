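"""Target curation: NVG selection, interval ranking, panel assembly, reference."""

import numpy as np
import pytest

import scdeplete as sd


# --- NVG selection -------------------------------------------------------


def _nvg_dataset(rng, n_genes=100, n_cells=60, depth_lam=8.0, special=()):
    """Poisson count matrix with optional planted gene columns.

    ``special`` maps row index -> per-cell count vector.
    """
    counts = rng.poisson(depth_lam, size=(n_genes, n_cells)).astype(np.int64)
    for idx, values in special:
        counts[idx, :] = values
    counts[0, :] += 1
    return sd.CountMatrix(
        counts, [f"g{i:03d}" for i in range(n_genes)], [f"c{i}" for i in range(n_cells)]
    )


def test_planted_housekeeping_gene_is_selected():
    """A gene with top-decile mean and minimal variance in every dataset is an NVG."""
    rng = np.random.default_rng(2)
    n_cells = 60
    datasets = [
        _nvg_dataset(
            rng,
            special=[
                # companions at comparable mean populate the top mean bin,
                # so low dispersion - not bin sparsity - drives the HVG call
                *((i, rng.poisson(40.0, n_cells)) for i in range(45, 50)),
                (50, np.full(n_cells, 40)),  # constant, high: the housekeeper
            ],
        )
        for _ in range(3)
    ]
    selected = sd.select_nvg(datasets, n_hvg=20, n_select=10)
    assert "g050" in selected


def test_hvg_in_any_dataset_is_excluded():
    """The gene with the highest mean is dropped if one dataset flags it variable."""
    rng = np.random.default_rng(12)
    n_cells = 60
    constant = np.full(n_cells, 60)
    spiky = np.zeros(n_cells, dtype=np.int64)
    spiky[::2] = 120  # same mean, extreme variance
    datasets = [
        _nvg_dataset(rng, special=[(50, constant)]),
        _nvg_dataset(rng, special=[(50, constant)]),
        _nvg_dataset(rng, special=[(50, spiky)]),
    ]
    selected = sd.select_nvg(datasets, n_hvg=20, n_select=10)
    assert "g050" not in selected


def test_single_dataset_degenerate_aggregation_is_mean_ranking():
    """With one dataset and n_select = everything, output is the non-HVG mean ranking."""
    import scanpy as sc

    rng = np.random.default_rng(7)
    m = _nvg_dataset(rng)
    n_hvg = 20
    selected = sd.select_nvg([m], n_hvg=n_hvg, n_select=m.n_genes)

    adata = sd.io_formats.counts_to_anndata(m)
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
    keep = ~adata.var["highly_variable"].to_numpy()
    means = np.asarray(adata.X.mean(axis=0)).ravel()
    expected = [g for g, _ in sorted(
        ((g, mu) for g, mu, k in zip(m.gene_ids, means, keep) if k),
        key=lambda t: (-t[1], t[0]),
    )]
    assert selected == expected  # dispersion ties may flag a few extra HVGs


def test_nvg_never_returns_a_variable_gene(small_spec):
    """No selected gene may sit in any dataset's top-HVG set."""
    import scanpy as sc

    datasets = [sd.simulate_counts(small_spec, seed) for seed in (2, 3)]
    n_hvg = 40
    selected = set(sd.select_nvg(datasets, n_hvg=n_hvg, n_select=30))
    for m in datasets:
        adata = sd.io_formats.counts_to_anndata(m)
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
        hvg = set(adata.var.index[adata.var["highly_variable"]])
        assert not (selected & hvg)


def test_nvg_requires_remainder():
    rng = np.random.default_rng(0)
    m = _nvg_dataset(rng, n_genes=30)
    with pytest.raises(ValueError):
        sd.select_nvg([m], n_hvg=30, n_select=5)


# --- genomic interval ranking -------------------------------------------


@pytest.fixture(scope="module")
def interval_world():
    spec = sd.LibrarySpec(
        n_cells=5, n_genes=6, depth=50, n_panel_genes=2,
        n_housekeeping=0, n_hvg_like=0, n_hotspots=3,
    )
    genome, annotation = sd.make_genome(spec, seed=4)
    return spec, genome, annotation, sd.hotspot_windows(spec), sd.contig_lengths(spec)


def test_shared_hotspot_ranks_first(interval_world):
    spec, genome, annotation, hotspots, lengths = interval_world
    contig, hs_start, hs_end = hotspots[0]

    def reads_for(seed):
        r = np.random.default_rng(seed)
        reads = [(contig, int(s), int(s) + 50) for s in r.integers(hs_start, hs_end - 50, 30)]
        # second dataset-specific hotspot, present in dataset 1 only
        if seed == 1:
            c2, s2, e2 = hotspots[1]
            reads += [(c2, int(s), int(s) + 50) for s in r.integers(s2, e2 - 50, 10)]
        return reads

    out = sd.rank_genomic_intervals(
        [reads_for(s) for s in (1, 2, 3)], annotation, lengths,
        window_size=500, n_shared=1, n_per_dataset=1,
    )
    assert hotspots[0] in out  # shared across all datasets
    assert hotspots[1] in out  # top dataset-specific window
    assert len(out) == 2


def test_reads_inside_protein_coding_genes_contribute_nothing(interval_world):
    spec, genome, annotation, hotspots, lengths = interval_world
    g = annotation.genes[spec.gene_ids()[0]]
    reads = [(g.contig, g.start + 10, g.start + 60)] * 100
    out = sd.rank_genomic_intervals([reads], annotation, lengths, 500, 10, 10)
    assert out == []


def test_empty_read_set_yields_empty_output(interval_world):
    _, _, annotation, _, lengths = interval_world
    assert sd.rank_genomic_intervals([[]], annotation, lengths, 500, 10, 10) == []


def test_selected_windows_never_overlap_protein_coding_genes(interval_world):
    spec, genome, annotation, hotspots, lengths = interval_world
    rng = np.random.default_rng(8)
    length = lengths["chr1"]
    reads = [
        [(("chr1"), int(s), int(s) + 50) for s in r.integers(0, length - 50, 400)]
        for r in (np.random.default_rng(s) for s in range(3))
    ]
    out = sd.rank_genomic_intervals(reads, annotation, lengths, 500, 20, 5)
    pc = [(g.start, g.end) for g in annotation.protein_coding()]
    for contig, s, e in out:
        assert not any(gs < e and ge > s for gs, ge in pc)


# --- panel assembly ------------------------------------------------------


def _ids(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


def test_panel_size_of_standard_category_sizes():
    panel = sd.assemble_panel(
        ribo_genes=_ids("RP", 90), mito_genes=_ids("MT-", 10), nvg_genes=_ids("NVG", 155)
    )
    assert panel.panel_size == 255


def test_duplicate_gene_is_deduplicated_with_warning(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="scdeplete"):
        panel = sd.assemble_panel(
            ribo_genes=["RPA", "SHARED"], mito_genes=[], nvg_genes=["SHARED", "NVG1"]
        )
    assert panel.panel_size == 3
    assert "SHARED" in panel.categories["ribo"]
    assert "SHARED" not in panel.categories["nvg"]
    assert any("already assigned" in r.message for r in caplog.records)


def test_panel_without_genes_is_an_error():
    with pytest.raises(ValueError):
        sd.assemble_panel([], [], [], [], intervals=[("c1", 0, 500)])


def test_panel_assembly_category_content_is_order_invariant():
    a = sd.assemble_panel(_ids("R", 5), _ids("M", 3), _ids("N", 7))
    b = sd.assemble_panel(_ids("R", 5)[::-1], _ids("M", 3)[::-1], _ids("N", 7)[::-1])
    assert {c: set(v) for c, v in a.categories.items()} == {
        c: set(v) for c, v in b.categories.items()
    }
    assert a.panel_size == b.panel_size


def test_overlapping_intervals_are_merged():
    panel = sd.assemble_panel(
        ["R1"], [], [], intervals=[("c1", 0, 500), ("c1", 400, 900), ("c2", 0, 100)]
    )
    assert panel.intervals == [("c1", 0, 900), ("c2", 0, 100)]


def test_panel_json_round_trip(tmp_path, small_panel):
    path = tmp_path / "panel.json"
    small_panel.to_json(path)
    loaded = sd.TargetPanel.from_json(path)
    assert loaded.categories == small_panel.categories
    assert loaded.intervals == small_panel.intervals


# --- depletion reference -------------------------------------------------


def _one_gene_world(span, contig_len=1000):
    rng = np.random.default_rng(9)
    genome = sd.SequenceSet({"c1": "".join(rng.choice(list("ACGT"), contig_len))})
    ann = sd.GeneAnnotation(
        {"g1": sd.GeneRecord("g1", "c1", span[0], span[1], "+", "protein_coding")},
        {"g1": [span]},
    )
    panel = sd.assemble_panel([], [], ["g1"])
    return genome, ann, panel


def test_reference_record_has_flanked_length():
    genome, ann, panel = _one_gene_world((200, 500))
    ref = sd.build_depletion_reference(panel, genome, ann, flank=100)
    assert len(ref["gene|g1"]) == 500  # 300 + 2 x 100


def test_reference_clips_at_contig_start():
    genome, ann, panel = _one_gene_world((0, 50))
    ref = sd.build_depletion_reference(panel, genome, ann, flank=100)
    assert len(ref["gene|g1"]) == 150


def test_missing_panel_gene_raises_lookup_error():
    genome, ann, _ = _one_gene_world((200, 500))
    panel = sd.assemble_panel([], [], ["g1", "ghost"])
    with pytest.raises(LookupError, match="ghost"):
        sd.build_depletion_reference(panel, genome, ann)


def test_full_panel_reference_length_matches_arithmetic_oracle(small_library, small_panel):
    genome, ann = small_library["genome"], small_library["annotation"]
    flank = 100
    ref = sd.build_depletion_reference(small_panel, genome, ann, flank)
    expected = 0
    for cat, pad in (("nvg", flank), ("mito", flank), ("ribo", flank), ("rrna", 0)):
        for gid in small_panel.categories[cat]:
            g = ann.genes[gid]
            clen = len(genome[g.contig])
            expected += min(clen, g.end + pad) - max(0, g.start - pad)
    expected += sum(e - s for _, s, e in small_panel.intervals)
    assert ref.total_length() == expected
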