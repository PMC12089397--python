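# Methods

This note documents the models and numerical choices behind
`scdeplete`: what each component assumes, which parameters matter, what
the synthetic generator does and does not emulate, and where the design
was genuinely open.

## Depletion model

The central assumption is complete removal: every molecule attributable
to a panel target is deleted, modelling a saturating Cas9 incubation.
Partial cleavage efficiency is deliberately out of scope.

**Count level.** `deplete_counts` treats each cell independently. With
`per_cell_depth="match"` the cell's original UMI total *n* is redrawn as
a multinomial over the non-panel genes with probabilities proportional
to the cell's own non-panel counts. This encodes "removed molecules are
replaced in proportion to relative abundance" and yields the closed
form E[informative fold change] = 1/(1 − f) for a targeted UMI share
*f*. Two exact invariants follow and are asserted in the test suite:
per-cell totals are conserved under `"match"`, and panel rows are
exactly zero. Cells whose counts were entirely panel-derived are
dropped, not imputed. Sampling is with replacement (multinomial)
because the replacement model is about the composition of an
effectively infinite molecular pool, whereas read downsampling
(`downsample_pairs`) is without replacement because it subsamples a
fixed, finite sequencing run.

A consequence worth stating explicitly: because the per-cell resampling
distribution is the cell's *observed* non-panel profile, matched-depth
depletion can never detect a gene the cell did not already have — genes
detected per cell can only shrink slightly. The complexity benefit of
depletion appears, as in a real experiment, when depletion happens
*before* the sampling bottleneck: a deep library is depleted (or not)
and both conditions are downsampled to the same reduced per-cell depth
(`deplete_counts` with an integer `per_cell_depth`). The control spends
part of its budget on targeted molecules; the depleted condition spends
all of it on informative ones. All directional comparisons (top-N UMI
concentration down, genes/UMI complexity up) use this depth-matched
construction.

**Read level.** `classify_reads` labels each read by canonical k-mer
containment against the per-category depletion reference (defaults
k = 21, θ = 0.5, category priority gene > interval > rRNA). This is a
deterministic desk-scale stand-in for the two-pass spliced alignment a
production pipeline would use; equivalence with an aligner is not
claimed, both parameters are configurable, and an externally produced
read→label table can be substituted. With the generator's reads (exact
unspliced substrings) containment is 1.0 for true targets and near 0
for everything else, so θ is uncritical on synthetic data; on real
reads spanning splice junctions θ trades sensitivity for specificity.

## Guide design

Defaults, with units and rationale:

| parameter | default | why |
| --- | --- | --- |
| GC bounds | 0.25–0.75 | symmetric, conventional manufacturability bounds for IVT guide pools |
| max homopolymer | 4 nt | runs ≥ 4 nt (notably TTTT, a Pol III terminator) are excluded |
| max dinucleotide tandem | 4 units | e.g. ATATATAT; matches common guide-QC practice |
| off-target mismatches | ≤ 3 | near-matches up to 3 mismatches in exonic exclusion sequence disqualify a guide |
| off-target PAM required | yes | cleavage requires NGG adjacency; toggleable since a conservative pipeline may ignore it |
| min inter-guide spacing | 30 nt | maximum-density packing with a spacing floor |

The off-target search is seed-and-extend with pigeonhole seeds: the
20-mer is split into `max_mismatches + 1` disjoint seeds (length
`20 // (m+1)`, i.e. 5 nt at m = 3), one of which must match exactly at
any locus within distance m; every seed hit is verified by a full
Hamming comparison. This is provably lossless, and the tests assert
result-identity with a position-by-position scan. A fixed-length
8-mer index was considered and rejected: 8-mer seeds are only
guaranteed to find matches up to 2 mismatches of a 20-mer.

On-target scoring is a pluggable registry. The default
`"position_weight"` scheme is a transparent fixed positional-nucleotide
weight table squashed through a logistic — it encodes commonly reported
SpCas9 base preferences (G favoured PAM-proximal, T disfavoured near
the PAM) but makes no claim of equivalence with any trained model;
`"uniform"` (constant 0.5) supports score-free selection. Selection is
greedy in descending score with deterministic tie-breaks (ascending
coordinate, then lexicographic protospacer); greedy interval packing is
optimal under uniform scores and 2-approximate in general, which the
tests check against exhaustive search at small n.

## Target curation

**Non-variable genes.** Per dataset: normalise per cell to 10,000
counts, log1p, exclude the top `n_hvg` genes by mean-binned normalised
dispersion (delegated to `scanpy.pp.highly_variable_genes`,
flavor `"seurat"`), rank the remainder by mean normalised expression.
Across datasets a gene's aggregate rank is its worst per-dataset rank —
worst-rank aggregation guarantees uniformly high abundance, which is
the property that makes removal safe. One caveat of the seurat flavor
at small gene counts: a gene alone in its mean bin receives a
normalised dispersion of 1.0 by convention and can be spuriously
flagged variable; at realistic gene counts bins are well populated.

**Genomic intervals.** Reads overlapping any protein-coding gene span
(≥ 1 bp) are discarded; the rest are counted into fixed 500-bp windows
by read start (O(1) binning; a read contributes to exactly one window).
A window's shared score is its *minimum* depth across datasets (strict
sharing); the top `n_shared` shared windows are taken, then the top
`n_per_dataset` dataset-specific windows each. Windows intersecting a
protein-coding gene are never returned. Defaults `n_shared=100`,
`n_per_dataset=10` are configuration, chosen as a round survey-scale
default.

**Panel assembly.** Categories are stored disjointly with precedence
rRNA > mito > ribo > NVG (a duplicated gene stays in the
higher-precedence category, with a warning). The depletion reference
extracts each protein-coding panel gene's unspliced genomic span plus a
100-bp flank per side (clipped at contig ends), each rRNA gene's exact
span, and each interval's sequence. Strand is ignored throughout
because Cas9 cuts double-stranded cDNA.

## Metrics

Top-N UMI fractions rank genes once, library-wide, by total UMIs
(per-cell ranking is available via a flag; the two differ only when
cells disagree strongly on their most abundant genes). Medians use the
midpoint convention. The Marchenko–Pastur component count standardises
genes (zero-variance genes dropped) after per-cell 10k normalisation
and log1p, takes eigenvalues of the gene-gene correlation via SVD
(scaled by 1/n_cells), and counts those above λ₊ = (1 + √γ)². No
sparsity or tracking corrections are applied; parity with refined
random-matrix tools is not claimed. Note that duplicating cells leaves
the spectrum unchanged but halves γ and thus lowers λ₊, so the raw
count can only grow under duplication — the meaningful invariant, and
the one tested, is that detected signal eigenvalues persist.

## Applicability scoring

Tau uses log2(x + 1) on TPM with an expression floor of 1 TPM (genes
whose maximum raw expression is below the floor are reported missing)
and a specificity flag at τ ≥ 0.8. All three choices are exposed as
parameters since published uses of the index vary. Binning is
equal-interval over [min, max] with the last bin right-closed and edge
ties resolved downward. Preranked enrichment is the weighted
Kolmogorov–Smirnov running sum with hit weights |statistic|^p
(default p = 1) and uniform miss decrements; the null is random
same-size gene sets (gene-label permutation — appropriate for a
preranked input), NES = ES / mean(|null ES| of the same sign), and the
FDR for a single query set reduces to its p-value. Only the p = 0
statistic is sign-symmetric under the null; the weighted ES has a
positive offset by construction, which is why calibration runs through
the permutation null rather than the raw ES.

## Off-target QC

Pseudobulks (per-gene totals) of control and depleted libraries are
compared after multinomially downsampling the larger to the smaller
total; log2FC uses pseudocount 1. No size-factor normalisation is
offered in this module, on purpose: depletion changes library
composition globally, and a size-factor model absorbs exactly the
effect being measured. Non-panel genes below the log2FC threshold
(−0.5 for experimental comparisons; −0.1 is a stricter choice for
in-silico ones) are flagged and partitioned into coordinate-overlap
genes — spans intersecting a flank-extended panel target — versus
sequence-similarity candidates, which deserve guide-level scrutiny.

## Synthetic generator

`LibrarySpec` defaults define the reference study conditions: 1,000
cells x 2,000 genes at 2,000 UMIs per cell, with 100 panel-like
abundant genes holding an expected 50% of UMIs — the regime where
matched-depth depletion doubles informative coverage. Base gene
abundance is log-normal (σ = 1); housekeeping genes get a 10x mean
boost with no extra cell-to-cell noise; HVG-like genes carry mean-one
multiplicative log-normal noise (σ = 1.5) so planted shares stay
unbiased. Extra read categories default to 10% rRNA carryover, 9%
hotspot-interval reads and 5% diffuse intergenic background, echoing
the read-composition medians reported for droplet 3' scRNA-seq
surveys. Genome layout (gene spans, window-aligned hotspots, background
stretches) is a deterministic function of the spec; sequence content is
a pure function of the seed, so identical seeds give byte-identical
FASTA/FASTQ.

What the generator does **not** emulate: sequencing errors and base
qualities, PCR duplicates, splice structure (reads come from unspliced
gene bodies, matching the depletion reference convention), doublets,
ambient RNA, and batch effects. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
robustness to these real-data artefacts.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic
data: oracle-equivalence suites use 20 seeds each on small fixtures
(hundreds of bases / tens of cells); calibration suites use 20–40
seeds; the re-allocation check uses the full 1,000 x 2,000 x 2,000
conditions over 20 replicates. Every source of randomness is an
explicit `numpy.random.default_rng` seed carried in function arguments
and logged into summaries; there is no global random state.

## Known limitations

- Read classification is k-mer containment, not spliced alignment;
  junction-spanning reads on real data will show partial containment.
- The NVG cutoff (how many genes to keep) and interval counts are
  configuration, not derived quantities; published panels depended on
  proprietary pipelines and specific reference builds, so exact
  published guide or gene counts are not reproduction targets.
- The MP component count uses the plain standardized-correlation edge;
  heavy sparsity can shift the noise spectrum.
- `flag_offtargets` is a naive thresholding of a single comparison;
  replicate-aware statistics are intentionally out of scope.
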