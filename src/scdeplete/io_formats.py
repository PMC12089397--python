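"""Readers, writers and the in-memory data model shared by all modules.

All genomic coordinates are held internally as 0-based half-open intervals.
BED records are native to that convention; GTF records (1-based inclusive)
are converted at the I/O boundary and nowhere else.

FASTQ quality strings are carried through verbatim but never interpreted:
no step of the toolkit uses base qualities.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("scdeplete")

VALID_BASES = frozenset("ACGTN")
# 10x Chromium 3' v3.1 geometry: 16 nt cell barcode + 12 nt UMI on R1.
DEFAULT_BARCODE_LEN = 16
DEFAULT_UMI_LEN = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class PairingError(ValueError):
    """R1/R2 FASTQ files disagree on read identity or count."""


class ConfigurationError(ValueError):
    """An invalid parameter or unknown configuration value."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sanitize(seq: str) -> str:
    """Upcase and map any non-ACGTN character to N."""
    seq = seq.upper()
    if set(seq) <= VALID_BASES:
        return seq
    return "".join(c if c in VALID_BASES else "N" for c in seq)


# ---------------------------------------------------------------------------
# Sequence sets (FASTA)
# ---------------------------------------------------------------------------


@dataclass
class SequenceSet:
    """An ordered mapping of sequence id -> uppercase A/C/G/T/N string."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise FormatError(f"sequence {name!r} is empty")
            if not set(seq) <= VALID_BASES:
                raise FormatError(f"sequence {name!r} contains characters outside ACGTN")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def items(self):
        return self.records.items()

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())


def load_sequences(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Lowercase bases are upcased and ambiguity codes (anything outside
    ACGTN) are mapped to N.
    """
    records: dict[str, str] = {}
    with _open_text(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: malformed FASTA header (expected '>')")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            records[rec.id] = _sanitize(str(rec.seq))
    return SequenceSet(records)


def write_sequences(seqs: SequenceSet, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        SeqIO.write(
            (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
            handle,
            "fasta",
        )


# ---------------------------------------------------------------------------
# Gene annotations (GTF / BED)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    biotype: str


@dataclass
class GeneAnnotation:
    """Gene and exon coordinates, 0-based half-open."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, g in self.genes.items():
            if not (0 <= g.start < g.end):
                raise FormatError(f"gene {gid}: invalid span ({g.start},{g.end})")
            for s, e in self.exons.get(gid, ()):
                if s < g.start or e > g.end:
                    raise FormatError(
                        f"gene {gid}: exon ({s},{e}) outside gene span ({g.start},{g.end})"
                    )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def protein_coding(self) -> list[GeneRecord]:
        return [g for g in self.genes.values() if g.biotype == "protein_coding"]


def load_annotation(path: str | Path) -> GeneAnnotation:
    """Read a GTF file with gene and exon features.

    GTF's 1-based inclusive coordinates are converted to the internal
    0-based half-open convention.  The ``gene_biotype`` (or ``gene_type``)
    attribute is retained when present.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: cannot parse GTF ({exc})") from exc

    genes: dict[str, GeneRecord] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("gene"):
        if "gene_id" not in feat.attributes:
            raise FormatError(f"{path}: gene feature without gene_id attribute")
        gid = feat.attributes["gene_id"][0]
        if gid in genes:
            raise FormatError(f"{path}: duplicate gene_id {gid!r}")
        biotype = (
            feat.attributes.get("gene_biotype", feat.attributes.get("gene_type", ["unknown"]))
        )[0]
        genes[gid] = GeneRecord(gid, feat.seqid, feat.start - 1, feat.end, feat.strand, biotype)
    for feat in db.features_of_type("exon"):
        if "gene_id" not in feat.attributes:
            raise FormatError(f"{path}: exon feature without gene_id attribute")
        gid = feat.attributes["gene_id"][0]
        exons.setdefault(gid, []).append((feat.start - 1, feat.end))
    if not genes:
        raise FormatError(f"{path}: no gene features found")
    return GeneAnnotation(genes, exons)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    """Write gene/exon features back out as GTF (1-based inclusive)."""
    with _open_text(path, "wt") as out:
        for gid, g in ann.genes.items():
            attrs = f'gene_id "{gid}"; gene_biotype "{g.biotype}";'
            out.write(
                f"{g.contig}\tscdeplete\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in ann.exons.get(gid, ()):
                out.write(
                    f"{g.contig}\tscdeplete\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def load_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED records (first three columns) as (contig, start, end)."""
    intervals: list[tuple[str, int, int]] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: BED line with fewer than 3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}: BED interval with start >= end")
            intervals.append((contig, start, end))
    return intervals


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path, names: Sequence[str] | None = None) -> None:
    with _open_text(path, "wt") as out:
        for i, (contig, start, end) in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            out.write(f"{contig}\t{start}\t{end}\t{name}\t0\t+\n")


# ---------------------------------------------------------------------------
# Barcoded read pairs (FASTQ)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    barcode: str
    umi: str
    cdna: str
    r1_qual: str | None = None
    r2_qual: str | None = None


@dataclass
class BarcodedReadSet:
    """Paired reads: R1 = cell barcode + UMI, R2 = cDNA."""

    pairs: list[ReadPair] = field(default_factory=list)
    barcode_len: int = DEFAULT_BARCODE_LEN
    umi_len: int = DEFAULT_UMI_LEN

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pairs:
            if len(p.barcode) != self.barcode_len or len(p.umi) != self.umi_len:
                raise FormatError(f"read {p.read_id}: barcode/UMI length mismatch")
            if p.read_id in seen:
                raise FormatError(f"duplicate read id {p.read_id!r}")
            seen.add(p.read_id)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[ReadPair]:
        return iter(self.pairs)


def load_read_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    barcode_len: int = DEFAULT_BARCODE_LEN,
    umi_len: int = DEFAULT_UMI_LEN,
) -> BarcodedReadSet:
    """Load paired FASTQ files into a :class:`BarcodedReadSet`.

    The barcode is R1[0:barcode_len], the UMI the following umi_len bases;
    the cDNA is the full R2 sequence.  Files must contain the same reads
    in the same order.
    """
    pairs: list[ReadPair] = []
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        it1 = SeqIO.parse(h1, "fastq")
        it2 = SeqIO.parse(h2, "fastq")
        for rec1 in it1:
            rec2 = next(it2, None)
            if rec2 is None:
                raise PairingError("R2 file has fewer records than R1")
            id1 = rec1.id.removesuffix("/1")
            id2 = rec2.id.removesuffix("/2")
            if id1 != id2:
                raise PairingError(f"read id mismatch: {rec1.id!r} vs {rec2.id!r}")
            seq1 = str(rec1.seq).upper()
            if len(seq1) < barcode_len + umi_len:
                raise FormatError(
                    f"read {id1}: R1 shorter than barcode+UMI ({len(seq1)} < {barcode_len + umi_len})"
                )
            pairs.append(
                ReadPair(
                    read_id=id1,
                    barcode=seq1[:barcode_len],
                    umi=seq1[barcode_len : barcode_len + umi_len],
                    cdna=str(rec2.seq).upper(),
                    r1_qual="".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"]),
                    r2_qual="".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"]),
                )
            )
        if next(it2, None) is not None:
            raise PairingError("R1 file has fewer records than R2")
    return BarcodedReadSet(pairs, barcode_len, umi_len)


def write_read_pairs(reads: BarcodedReadSet, r1_path: str | Path, r2_path: str | Path) -> None:
    """Write a read set back out as an R1/R2 FASTQ pair.

    Qualities are emitted verbatim when present, otherwise as constant 'I'.
    """
    with _open_text(r1_path, "wt") as o1, _open_text(r2_path, "wt") as o2:
        for p in reads:
            r1seq = p.barcode + p.umi
            q1 = p.r1_qual if p.r1_qual is not None else "I" * len(r1seq)
            q2 = p.r2_qual if p.r2_qual is not None else "I" * len(p.cdna)
            o1.write(f"@{p.read_id}\n{r1seq}\n+\n{q1}\n")
            o2.write(f"@{p.read_id}\n{p.cdna}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# UMI count matrices (MatrixMarket)
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x cell UMI counts with gene/cell labels.

    ``counts`` is a dense non-negative integer array of shape
    (n_genes, n_cells).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_barcodes)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene ids are not unique")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise FormatError("cell barcodes are not unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Indices of the given genes; genes absent from the matrix are skipped."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids if g in lookup], dtype=int)


def load_counts(
    matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> CountMatrix:
    """Read a MatrixMarket triplet matrix plus gene/barcode label files."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:
        raise FormatError(f"{matrix_path}: cannot parse MatrixMarket ({exc})") from exc
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if dense.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {dense.shape} but label files give "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    if np.any(dense != np.round(dense)) or np.any(dense < 0):
        raise FormatError(f"{matrix_path}: entries must be non-negative integers")
    return CountMatrix(dense.astype(np.int64), genes, barcodes)


def write_counts(
    matrix: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(matrix.counts), field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in matrix.cell_barcodes))


def counts_to_anndata(matrix: CountMatrix):
    """View a CountMatrix as an AnnData (cells x genes) for toolkit interop."""
    import anndata

    return anndata.AnnData(
        X=scipy.sparse.csr_matrix(matrix.counts.T.astype(np.float32)),
        obs=pd.DataFrame(index=matrix.cell_barcodes),
        var=pd.DataFrame(index=matrix.gene_ids),
    )
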