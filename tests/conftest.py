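import numpy as np
import pytest

import scdeplete as sd


@pytest.fixture(scope="session")
def small_spec() -> sd.LibrarySpec:
    """A desk-scale library: 50 cells x 200 genes, panel holds half the UMIs."""
    return sd.LibrarySpec(
        n_cells=50,
        n_genes=200,
        depth=500,
        n_panel_genes=20,
        n_housekeeping=10,
        n_hvg_like=20,
    )


@pytest.fixture(scope="session")
def small_library(small_spec):
    """Genome, annotation, counts, reads and truth labels for one seed."""
    genome, annotation = sd.make_genome(small_spec, seed=1)
    matrix = sd.simulate_counts(small_spec, seed=1)
    reads, truth = sd.simulate_reads(matrix, genome, annotation, small_spec, seed=1)
    return {
        "spec": small_spec,
        "genome": genome,
        "annotation": annotation,
        "matrix": matrix,
        "reads": reads,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_panel(small_spec) -> sd.TargetPanel:
    """Panel targeting the spec's abundant genes plus its hotspot windows."""
    return sd.assemble_panel(
        ribo_genes=[],
        mito_genes=[],
        nvg_genes=small_spec.panel_gene_ids(),
        rrna_genes=small_spec.rrna_ids(),
        intervals=sd.hotspot_windows(small_spec),
    )


def random_count_matrix(
    rng: np.random.Generator, n_genes: int = 30, n_cells: int = 20, lam: float = 5.0
) -> sd.CountMatrix:
    counts = rng.poisson(lam, size=(n_genes, n_cells)).astype(np.int64)
    counts[0, :] += 1  # keep every cell non-empty
    return sd.CountMatrix(
        counts,
        [f"g{i}" for i in range(n_genes)],
        [f"c{i}" for i in range(n_cells)],
    )
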