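"""Core domain types and pre-alignment fragment processing.

A *fragment* is a sequenced DNA molecule after paired-end merging: the unit
that all downstream screening operates on.  This module holds the domain
types shared across the package and the three pre-alignment stages of the
screening pipeline: strict double-index demultiplexing, PCR-duplicate
collapse, and minimum-length filtering.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open.  SAM input (1-based,
inclusive) is converted at the I/O boundary.  Reverse-strand alignments
store read bases in reference-forward orientation (as in SAM); read-
orientation views are computed on demand via :func:`oriented_read_columns`.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGT characters map to N."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Fragment:
    """A deduplicated sequenced DNA molecule.

    ``multiplicity`` counts how many identical raw copies were collapsed
    into this record during duplicate removal.
    """

    id: str
    sequence: str
    multiplicity: int = 1
    library_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"fragment {self.id}: empty sequence")
        if self.multiplicity < 1:
            raise ValueError(f"fragment {self.id}: multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IndexPair:
    """Expected (i7, i5) double-index combination for one library."""

    i7: str
    i5: str
    library_id: str


# An alignment column: (reference position or None, read position or None,
# read base or None).  Read positions are SAM query coordinates, i.e. they
# increase along the reference-forward representation of the read.
PairColumn = tuple[Optional[int], Optional[int], Optional[str]]


@dataclass
class AlignedFragment:
    """A fragment's placement on a reference mitogenome.

    ``pairs`` lists alignment columns in reference order.  For
    reverse-strand alignments the stored read bases are the
    reference-forward (SAM SEQ) representation; the biological read
    orientation is recovered with :func:`oriented_read_columns`.
    ``masked_read_positions`` holds query coordinates hidden from tallies
    and consensus (set by deamination masking).
    """

    fragment_id: str
    reference_id: str
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    mapping_quality: int
    pairs: list[PairColumn]
    library_id: str = ""
    masked_read_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.ref_start < self.ref_end:
            raise ValueError(
                f"{self.fragment_id}: ref_start must be < ref_end "
                f"({self.ref_start}, {self.ref_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.fragment_id}: strand must be '+' or '-'")

    @property
    def read_length(self) -> int:
        return sum(1 for _, q, _ in self.pairs if q is not None)

    def query_sequence(self) -> str:
        """Reference-forward read sequence (SAM SEQ)."""
        return "".join(b for _, q, b in self.pairs if q is not None)


def oriented_read_columns(aln: AlignedFragment):
    """Yield match columns of ``aln`` in biological read orientation.

    Yields ``(read_pos5, ref_pos, read_base)`` for every column where both
    a reference and a read position are present; ``read_pos5`` is the
    0-based distance of the base from the read's 5' end, and ``read_base``
    is in read orientation (complemented for reverse-strand alignments).
    Insertion/deletion columns are skipped.
    """
    n = aln.read_length
    matches = [(r, q, b) for r, q, b in aln.pairs if r is not None and q is not None]
    if aln.strand == "+":
        for r, q, b in matches:
            yield q, r, b
    else:
        for r, q, b in reversed(matches):
            yield n - 1 - q, r, b.translate(COMPLEMENT)


@dataclass
class PipelineParams:
    """Every numeric constant of the screening and placement pipeline.

    Defaults implement the study's filtering scheme: fragments of at least
    35 bp seen at least twice; a family present given >= 3 fragments and
    >= 1% of identifiable fragments; mapping quality >= 25; terminal C->T
    tested against a 10% null; consensus requiring coverage >= 2 and a
    2/3 majority; deamination masking over the terminal 3 alignment
    positions; relaxed informative sites at a 90% fixation threshold.
    """

    min_length: int = 35
    min_multiplicity: int = 2
    min_family_fragments: int = 3
    min_family_pct: float = 1.0
    min_mq: int = 25
    damage_null_rate: float = 0.10
    alpha: float = 0.05
    min_coverage: int = 2
    majority_fraction: Fraction = Fraction(2, 3)
    mask_terminal: int = 3
    group_fixed_fraction: float = 0.90
    profile_window: int = 15
    flank_window: int = 10

    def __post_init__(self) -> None:
        for name in ("damage_null_rate", "alpha", "group_fixed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "min_length", "min_multiplicity", "min_family_fragments",
            "min_mq", "min_coverage", "mask_terminal",
            "profile_window", "flank_window",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        mf = Fraction(self.majority_fraction)
        if not Fraction(1, 2) < mf <= 1:
            raise ValueError("majority_fraction must be in (1/2, 1]")
        object.__setattr__(self, "majority_fraction", mf)


@dataclass
class DemuxResult:
    """Per-library fragments plus the tally of index-mismatched reads."""

    by_library: dict[str, list[Fragment]]
    n_discarded: int


def demultiplex(
    raw_reads: Iterable[tuple[str, str, str, str]],
    index_table: Sequence[IndexPair],
) -> DemuxResult:
    """Assign reads to libraries by exact double-index match.

    A read ``(id, sequence, observed_i7, observed_i5)`` is assigned to a
    library iff its observed index pair equals that library's expected pair
    character-for-character; any mismatch discards the read.  No mismatch
    tolerance is offered: only exact double-index combinations identify a
    library.

    Raises
    ------
    ValueError
        If two libraries share the same (i7, i5) combination.
    """
    lookup: dict[tuple[str, str], str] = {}
    for pair in index_table:
        key = (pair.i7, pair.i5)
        if key in lookup and lookup[key] != pair.library_id:
            raise ValueError(
                f"duplicate index pair {key} for libraries "
                f"{lookup[key]!r} and {pair.library_id!r}"
            )
        lookup[key] = pair.library_id
    by_library: dict[str, list[Fragment]] = {p.library_id: [] for p in index_table}
    discarded = 0
    for read_id, seq, i7, i5 in raw_reads:
        lib = lookup.get((i7, i5))
        if lib is None:
            discarded += 1
            continue
        by_library[lib].append(
            Fragment(id=read_id, sequence=seq.upper(), library_id=lib)
        )
    return DemuxResult(by_library=by_library, n_discarded=discarded)


def filter_length(fragments: Sequence[Fragment], min_length: int) -> list[Fragment]:
    """Keep fragments of at least ``min_length`` bp, preserving order."""
    return [f for f in fragments if len(f.sequence) >= min_length]


def collapse_duplicates(
    fragments: Sequence[Fragment],
    mode: str = "sequence",
    alignments: Optional[Mapping[str, AlignedFragment]] = None,
    min_multiplicity: int = 2,
) -> list[Fragment]:
    """Collapse PCR duplicates.

    ``sequence`` mode removes exact sequence duplicates, keeping one record
    per distinct sequence with its copy count as multiplicity, and retains
    only fragments seen at least ``min_multiplicity`` times — discarding
    singletons suppresses both sequencing errors and spurious molecules.

    ``coordinates`` mode collapses by alignment position instead: one
    representative per (reference, start, end, strand) key, with no
    multiplicity threshold.  The representative carries the most frequent
    sequence for the key (copy-weighted; ties broken lexicographically),
    so isolated sequencing errors do not propagate.

    Raises
    ------
    ValueError
        Coordinates mode without an alignment for every fragment.
    """
    if mode == "sequence":
        order: list[str] = []
        groups: dict[str, list[Fragment]] = defaultdict(list)
        for f in fragments:
            if f.sequence not in groups:
                order.append(f.sequence)
            groups[f.sequence].append(f)
        out = []
        for seq in order:
            members = groups[seq]
            total = sum(m.multiplicity for m in members)
            if total >= min_multiplicity:
                out.append(replace(members[0], multiplicity=total))
        return out

    if mode == "coordinates":
        if alignments is None:
            raise ValueError("coordinates mode requires alignments")
        order2: list[tuple] = []
        groups2: dict[tuple, list[Fragment]] = defaultdict(list)
        for f in fragments:
            aln = alignments.get(f.id)
            if aln is None:
                raise ValueError(f"no alignment for fragment {f.id}")
            key = (aln.reference_id, aln.ref_start, aln.ref_end, aln.strand)
            if key not in groups2:
                order2.append(key)
            groups2[key].append(f)
        out = []
        for key in order2:
            members = groups2[key]
            tally: Counter[str] = Counter()
            for m in members:
                tally[m.sequence] += m.multiplicity
            best = min(tally, key=lambda s: (-tally[s], s))
            rep = next(m for m in members if m.sequence == best)
            out.append(replace(rep, multiplicity=sum(tally.values())))
        return out

    raise ValueError(f"unknown duplicate-collapse mode {mode!r}")
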