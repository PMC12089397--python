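"""sgRNA protospacer enumeration, filtering, scoring and spaced selection.

The design funnel mirrors standard SpCas9 guide-pool practice: enumerate
every 20-mer 5' of an NGG PAM on both strands, drop candidates with
extreme GC content, long homopolymers or dinucleotide tandem repeats,
discard anything with a near-match (Hamming distance <= 3 by default) in
an exclusion sequence set, then greedily pick high-scoring guides subject
to a minimum inter-guide spacing.

On-target activity prediction is a pluggable scorer.  The default
``"position_weight"`` scheme is a fixed positional-nucleotide weight
table (a transparent heuristic favouring the base preferences commonly
reported for SpCas9, e.g. G at the PAM-proximal position and depletion of
T near the PAM); it makes no claim of equivalence with any proprietary
or published machine-learned model.  A ``"uniform"`` scheme returning
0.5 is provided for pipelines that want score-free selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import ConfigurationError, SequenceSet, reverse_complement

logger = logging.getLogger("scdeplete")

PROTOSPACER_LEN = 20
PAM_LEN = 3

DEFAULT_GC_MIN = 0.25
DEFAULT_GC_MAX = 0.75
DEFAULT_MAX_HOMOPOLYMER = 4  # exclude runs >= 4 nt
DEFAULT_MAX_DINUCLEOTIDE_UNITS = 4  # exclude >= 4 tandem repeats of a 2-mer
DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MIN_SPACING = 30


@dataclass(frozen=True)
class GuideCandidate:
    """One 20-nt protospacer with its PAM and bookkeeping.

    ``start`` is the 0-based coordinate of the protospacer span's leftmost
    base on the + strand of ``contig``, for either strand.
    """

    protospacer: str
    pam: str
    contig: str
    start: int
    strand: str
    gc_fraction: float
    max_homopolymer: int
    max_dinucleotide_units: int
    on_target_score: float = 0.0
    offtarget_hits: int = 0

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")


@dataclass
class GuidePanel:
    """Selected guides grouped per target sequence."""

    guides: list[GuideCandidate] = field(default_factory=list)
    per_target: dict[str, list[GuideCandidate]] = field(default_factory=dict)
    min_spacing: int = DEFAULT_MIN_SPACING

    def __post_init__(self) -> None:
        for g in self.guides:
            if g.offtarget_hits > 0:
                raise ValueError(f"guide at {g.contig}:{g.start} has off-target hits")
        for contig, guides in self.per_target.items():
            starts = sorted(g.start for g in guides)
            for a, b in zip(starts, starts[1:]):
                if b - a < self.min_spacing:
                    raise ValueError(
                        f"guides on {contig} closer than min_spacing ({b - a} < {self.min_spacing})"
                    )

    def __len__(self) -> int:
        return len(self.guides)


def _longest_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _longest_dinucleotide_units(seq: str) -> int:
    """Longest perfect tandem repeat of a 2-mer with distinct bases, in units."""
    best = 0
    for phase in (0, 1):
        i = phase
        while i + 2 <= len(seq):
            unit = seq[i : i + 2]
            if unit[0] == unit[1]:
                i += 2
                continue
            units = 1
            j = i + 2
            while j + 2 <= len(seq) and seq[j : j + 2] == unit:
                units += 1
                j += 2
            best = max(best, units)
            i = j if units > 1 else i + 2
    return best


def _make_candidate(protospacer: str, pam: str, contig: str, start: int, strand: str) -> GuideCandidate:
    return GuideCandidate(
        protospacer=protospacer,
        pam=pam,
        contig=contig,
        start=start,
        strand=strand,
        gc_fraction=(protospacer.count("G") + protospacer.count("C")) / PROTOSPACER_LEN,
        max_homopolymer=_longest_homopolymer(protospacer),
        max_dinucleotide_units=_longest_dinucleotide_units(protospacer),
    )


def enumerate_protospacers(targets: SequenceSet) -> list[GuideCandidate]:
    """Find every 20-mer immediately 5' of an NGG PAM on both strands.

    Minus-strand candidates carry the protospacer as the reverse complement,
    with ``start`` giving the + strand coordinate of the leftmost base of
    the protospacer span.  Candidates containing N are excluded.
    """
    out: list[GuideCandidate] = []
    for contig, seq in targets.items():
        length = len(seq)
        # + strand: protospacer seq[i:i+20], PAM seq[i+20:i+23]
        for i in range(length - PROTOSPACER_LEN - PAM_LEN + 1):
            pam = seq[i + PROTOSPACER_LEN : i + PROTOSPACER_LEN + PAM_LEN]
            if pam[1] == "G" == pam[2] and pam[0] != "N":
                proto = seq[i : i + PROTOSPACER_LEN]
                if "N" not in proto:
                    out.append(_make_candidate(proto, pam, contig, i, "+"))
        # - strand: CCN at seq[j:j+3] means NGG on the reverse complement,
        # protospacer is revcomp(seq[j+3 : j+23]), occupying + span [j+3, j+23)
        for j in range(length - PROTOSPACER_LEN - PAM_LEN + 1):
            if seq[j] == "C" == seq[j + 1] and seq[j + 2] != "N":
                window = seq[j + PAM_LEN : j + PAM_LEN + PROTOSPACER_LEN]
                if "N" not in window:
                    out.append(
                        _make_candidate(
                            reverse_complement(window),
                            reverse_complement(seq[j : j + PAM_LEN]),
                            contig,
                            j + PAM_LEN,
                            "-",
                        )
                    )
    return out


def filter_composition(
    candidates: list[GuideCandidate],
    gc_min: float = DEFAULT_GC_MIN,
    gc_max: float = DEFAULT_GC_MAX,
    max_homopolymer: int = DEFAULT_MAX_HOMOPOLYMER,
    max_dinucleotide_units: int = DEFAULT_MAX_DINUCLEOTIDE_UNITS,
) -> list[GuideCandidate]:
    """Drop candidates with extreme GC, long homopolymers or dinucleotide repeats.

    A candidate survives when gc_min <= GC <= gc_max, its longest single-base
    run is shorter than ``max_homopolymer`` and its longest perfect
    dinucleotide tandem is shorter than ``max_dinucleotide_units`` repeats.
    """
    if not (0 <= gc_min < gc_max <= 1):
        raise ConfigurationError(f"invalid GC bounds ({gc_min}, {gc_max})")
    return [
        c
        for c in candidates
        if gc_min <= c.gc_fraction <= gc_max
        and c.max_homopolymer < max_homopolymer
        and c.max_dinucleotide_units < max_dinucleotide_units
    ]


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def count_offtargets(
    candidate: GuideCandidate,
    exclusion: SequenceSet,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    require_pam: bool = True,
) -> int:
    """Count near-matches of the protospacer in an exclusion sequence set.

    A hit is any position (either strand) where the protospacer aligns with
    Hamming distance <= ``max_mismatches`` and, when ``require_pam``, an NGG
    sits immediately 3' of the aligned 20-mer.  Uses pigeonhole seeding: the
    protospacer is split into ``max_mismatches + 1`` disjoint seeds, one of
    which must match exactly at any qualifying locus; every seed hit is then
    verified by a full Hamming comparison, so the result is identical to a
    position-by-position scan.
    """
    proto = candidate.protospacer
    n_seeds = max_mismatches + 1
    seed_len = PROTOSPACER_LEN // n_seeds
    seeds = [(i * seed_len, proto[i * seed_len : (i + 1) * seed_len]) for i in range(n_seeds)]

    hits = 0
    for _, refseq in exclusion.items():
        for strand_seq in (refseq, reverse_complement(refseq)):
            index = _seed_index(strand_seq, seed_len)
            checked: set[int] = set()
            for offset, seed in seeds:
                for pos in index.get(seed, ()):
                    start = pos - offset
                    if start < 0 or start + PROTOSPACER_LEN > len(strand_seq):
                        continue
                    if start in checked:
                        continue
                    checked.add(start)
                    if _hamming(proto, strand_seq[start : start + PROTOSPACER_LEN]) > max_mismatches:
                        continue
                    if require_pam:
                        pam = strand_seq[start + PROTOSPACER_LEN : start + PROTOSPACER_LEN + PAM_LEN]
                        if len(pam) < PAM_LEN or pam[1] != "G" or pam[2] != "G":
                            continue
                    hits += 1
    return hits


# Fixed positional-nucleotide weight table for the default scorer: a
# transparent heuristic encoding commonly reported SpCas9 base preferences
# (G favoured at the PAM-proximal end, T disfavoured near the PAM, mild
# preferences elsewhere).  Position 0 is PAM-distal, 19 PAM-proximal.
_POSITION_WEIGHTS: dict[int, dict[str, float]] = {
    0: {"G": 0.1, "T": -0.1},
    3: {"C": 0.1},
    4: {"C": 0.15, "T": -0.1},
    5: {"A": 0.1},
    10: {"A": 0.1, "T": -0.15},
    13: {"G": 0.1, "T": -0.1},
    15: {"C": 0.15, "G": 0.1, "T": -0.2},
    16: {"T": -0.2},
    17: {"G": 0.2, "A": -0.1},
    18: {"C": -0.2, "T": -0.2},
    19: {"G": 0.3, "C": -0.3, "T": -0.2},
}


def _position_weight_score(protospacer: str) -> float:
    total = sum(
        _POSITION_WEIGHTS.get(i, {}).get(base, 0.0) for i, base in enumerate(protospacer)
    )
    return float(1.0 / (1.0 + np.exp(-2.0 * total)))


SCORING_SCHEMES = {
    "position_weight": _position_weight_score,
    "uniform": lambda protospacer: 0.5,
}


def score_on_target(candidate: GuideCandidate, scheme: str = "position_weight") -> float:
    """Deterministic on-target activity score in [0, 1] for a candidate."""
    if scheme not in SCORING_SCHEMES:
        raise ConfigurationError(
            f"unknown scoring scheme {scheme!r}; known: {sorted(SCORING_SCHEMES)}"
        )
    return SCORING_SCHEMES[scheme](candidate.protospacer)


def score_candidates(
    candidates: list[GuideCandidate], scheme: str = "position_weight"
) -> list[GuideCandidate]:
    return [replace(c, on_target_score=score_on_target(c, scheme)) for c in candidates]


def select_spaced_guides(
    candidates: list[GuideCandidate],
    min_spacing: int = DEFAULT_MIN_SPACING,
    max_per_target: int | None = None,
) -> GuidePanel:
    """Greedy maximum-density selection under a minimum inter-guide spacing.

    Candidates are taken in descending on-target score (ties broken by
    ascending start coordinate, then lexicographic protospacer); a candidate
    is kept only when its start is >= ``min_spacing`` away from every
    already-selected start on the same target.  Candidates must already be
    composition- and off-target-filtered.
    """
    by_target: dict[str, list[GuideCandidate]] = {}
    for c in candidates:
        if c.offtarget_hits > 0:
            raise ValueError("select_spaced_guides requires off-target-filtered candidates")
        by_target.setdefault(c.contig, []).append(c)

    selected: dict[str, list[GuideCandidate]] = {}
    for contig, group in by_target.items():
        group.sort(key=lambda c: (-c.on_target_score, c.start, c.protospacer))
        chosen: list[GuideCandidate] = []
        for c in group:
            if max_per_target is not None and len(chosen) >= max_per_target:
                break
            if all(abs(c.start - s.start) >= min_spacing for s in chosen):
                chosen.append(c)
        chosen.sort(key=lambda c: c.start)
        selected[contig] = chosen

    all_guides = [g for group in selected.values() for g in group]
    logger.info("selected %d guides across %d targets", len(all_guides), len(selected))
    return GuidePanel(all_guides, selected, min_spacing)


def design_guides(
    targets: SequenceSet,
    exclusion: SequenceSet | None = None,
    gc_min: float = DEFAULT_GC_MIN,
    gc_max: float = DEFAULT_GC_MAX,
    max_homopolymer: int = DEFAULT_MAX_HOMOPOLYMER,
    max_dinucleotide_units: int = DEFAULT_MAX_DINUCLEOTIDE_UNITS,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    require_pam: bool = True,
    scheme: str = "position_weight",
    min_spacing: int = DEFAULT_MIN_SPACING,
    max_per_target: int | None = None,
) -> GuidePanel:
    """Run the whole design funnel: enumerate, filter, score, select."""
    cands = enumerate_protospacers(targets)
    n0 = len(cands)
    cands = filter_composition(cands, gc_min, gc_max, max_homopolymer, max_dinucleotide_units)
    n1 = len(cands)
    if exclusion is not None:
        kept = []
        for c in cands:
            hits = count_offtargets(c, exclusion, max_mismatches, require_pam)
            if hits == 0:
                kept.append(c)
        cands = kept
    n2 = len(cands)
    cands = score_candidates(cands, scheme)
    panel = select_spaced_guides(cands, min_spacing, max_per_target)
    logger.info(
        "design funnel: %d enumerated -> %d composition -> %d off-target -> %d selected",
        n0, n1, n2, len(panel),
    )
    return panel
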