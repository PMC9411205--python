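"""Phylogenetic placement via informative sites and partial consensus calling.

Within a family's mitogenome diversity, some alignment columns are
(nearly) fixed within one genus-level group and different in (nearly) all
other genomes — *phylogenetically informative positions*.  Short ancient
fragments overlapping such positions vote for the group whose diagnostic
base they carry.  Because terminal deamination would masquerade as
derived T (forward strand) or A (reverse strand) alleles, terminal T/A
bases are masked before any tally.  The same masked alignments support a
majority-vote partial consensus mitogenome.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import pandas as pd

from .fragments import AlignedFragment

VALID_BASES = frozenset("ACGT")


@dataclass
class GroupedMSA:
    """A multiple sequence alignment with per-sequence group labels.

    ``reference_id`` names the alignment member anchoring the coordinate
    system: informative sites are reported in that sequence's ungapped
    0-based coordinates, the same coordinates short fragments are aligned
    to.
    """

    names: list[str]
    rows: list[str]
    reference_id: str
    groups: dict[str, str]  # name -> group label ("ungrouped" allowed)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        ncol = {len(r) for r in self.rows}
        if len(ncol) > 1:
            raise ValueError("MSA rows have unequal length")
        if self.reference_id not in self.names:
            raise ValueError(f"reference {self.reference_id!r} not in MSA")
        for n in self.names:
            self.groups.setdefault(n, "ungrouped")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def reference_row(self) -> str:
        return self.rows[self.names.index(self.reference_id)]

    def reference_columns(self) -> list[tuple[int, int]]:
        """(msa_column, reference_position) for non-gap reference columns."""
        out = []
        pos = 0
        for col, ch in enumerate(self.reference_row()):
            if ch != "-":
                out.append((col, pos))
                pos += 1
        return out


def parse_groups(
    sequence_names: Sequence[str],
    rule: str = "genus_token",
    mapping_table: Optional[Mapping[str, str]] = None,
) -> dict[str, str]:
    """Label each sequence with its taxon group.

    ``genus_token`` takes the organism's genus from the sequence name,
    assumed formatted as ``<accession> <Genus> <species...>``; names with
    no organism token are labelled ``ungrouped``.  ``mapping_table`` uses
    an explicit name-or-accession -> group mapping and raises if a
    sequence is missing from it.
    """
    labels: dict[str, str] = {}
    if rule == "genus_token":
        for name in sequence_names:
            tokens = name.split()
            if len(tokens) >= 2:
                labels[name] = tokens[1]
            else:
                warnings.warn(f"no organism token in {name!r}; labelled ungrouped")
                labels[name] = "ungrouped"
        return labels
    if rule == "mapping_table":
        if mapping_table is None:
            raise ValueError("mapping_table rule requires a table")
        for name in sequence_names:
            acc = name.split()[0]
            if name in mapping_table:
                labels[name] = mapping_table[name]
            elif acc in mapping_table:
                labels[name] = mapping_table[acc]
            else:
                raise ValueError(f"sequence {name!r} missing from mapping table")
        return labels
    raise ValueError(f"unknown grouping rule {rule!r}")


@dataclass(frozen=True)
class InformativeSite:
    """A reference position diagnostic for one taxon group."""

    ref_position: int  # 0-based on the reference sequence
    group: str
    diagnostic_base: str
    mode: str  # "strict" | "frequency"
    in_group_fraction: float
    out_group_differing_fraction: float


def find_informative_sites(
    msa: GroupedMSA,
    mode: str = "strict",
    fraction: float = 0.90,
    min_group_sequences: int = 2,
    min_out_sequences: int = 2,
) -> list[InformativeSite]:
    """Scan reference-anchored MSA columns for group-diagnostic bases.

    For each group and column, the modal A/C/G/T base among valid group
    members is the candidate diagnostic base.  ``strict`` mode requires
    every valid member to carry it and every valid non-member to differ;
    ``frequency`` mode relaxes both requirements to at least ``fraction``
    (boundary inclusive).  Gap or ambiguous rows leave both denominators.
    Columns that are gaps in the reference are skipped (a fragment aligned
    to the reference cannot overlap them), as are columns with fewer than
    ``min_group_sequences`` valid members or ``min_out_sequences`` valid
    non-members.
    """
    if mode not in ("strict", "frequency"):
        raise ValueError(f"unknown mode {mode!r}")
    group_names = sorted(
        {g for g in msa.groups.values() if g != "ungrouped"}
    )
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups with sequences")
    member_rows = {
        g: [r for n, r in zip(msa.names, msa.rows) if msa.groups[n] == g]
        for g in group_names
    }
    sites: list[InformativeSite] = []
    for col, ref_pos in msa.reference_columns():
        column = [row[col].upper() for row in msa.rows]
        by_group: dict[str, list[str]] = defaultdict(list)
        for name, base in zip(msa.names, column):
            if base in VALID_BASES:
                by_group[msa.groups[name]].append(base)
        for g in group_names:
            ingroup = by_group.get(g, [])
            outgroup = [
                b for other, bases in by_group.items() if other != g for b in bases
            ]
            if len(ingroup) < min_group_sequences or len(outgroup) < min_out_sequences:
                continue
            counts = Counter(ingroup)
            base = min(counts, key=lambda b: (-counts[b], b))
            in_frac = counts[base] / len(ingroup)
            out_diff = sum(b != base for b in outgroup) / len(outgroup)
            if mode == "strict":
                ok = in_frac == 1.0 and out_diff == 1.0
            else:
                ok = in_frac >= fraction and out_diff >= fraction
            if ok:
                sites.append(
                    InformativeSite(ref_pos, g, base, mode, in_frac, out_diff)
                )
    return sites


def sites_to_table(sites: Sequence[InformativeSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_position": s.ref_position,
                "group": s.group,
                "base": s.diagnostic_base,
                "mode": s.mode,
                "in_group_fraction": s.in_group_fraction,
                "out_group_differing_fraction": s.out_group_differing_fraction,
            }
            for s in sites
        ],
        columns=[
            "ref_position", "group", "base", "mode",
            "in_group_fraction", "out_group_differing_fraction",
        ],
    )


def mask_damage(aln: AlignedFragment, mask_terminal: int = 3) -> AlignedFragment:
    """Flag potentially deaminated terminal bases as masked.

    Within the first and last ``mask_terminal`` alignment positions, T
    bases on forward-strand and A bases on reverse-strand alignments
    (reference-forward representation) are masked: a genuine derived
    allele and a deamination artefact are indistinguishable there.
    Masked columns stay in the record but become invisible to support
    tallies and consensus calling.
    """
    read_cols = [(q, b) for _, q, b in aln.pairs if q is not None]
    m = len(read_cols)
    target = "T" if aln.strand == "+" else "A"
    masked = set(aln.masked_read_positions)
    for idx, (q, b) in enumerate(read_cols):
        if idx < mask_terminal or idx >= m - mask_terminal:
            if b == target:
                masked.add(q)
    return replace(aln, masked_read_positions=frozenset(masked))


@dataclass(frozen=True)
class SupportTally:
    group: str
    matches: int
    overlaps: int


def tally_support(
    alignments: Sequence[AlignedFragment],
    sites: Sequence[InformativeSite],
    reference_length: Optional[int] = None,
) -> list[SupportTally]:
    """Count fragment observations at informative positions, per group.

    An *overlap* is a (fragment, site) pair where the fragment carries an
    unmasked valid base at the site's reference position; a *match* is an
    overlap whose base equals the site's diagnostic base.  One fragment
    spanning several sites contributes several observations.  Alignments
    should already be deamination-masked.
    """
    if reference_length is not None:
        for s in sites:
            if s.ref_position >= reference_length:
                raise ValueError(
                    f"site at {s.ref_position} beyond reference length {reference_length}"
                )
    by_pos: dict[int, list[InformativeSite]] = defaultdict(list)
    for s in sites:
        by_pos[s.ref_position].append(s)
    matches: Counter[str] = Counter()
    overlaps: Counter[str] = Counter()
    for aln in alignments:
        for r, q, b in aln.pairs:
            if r is None or q is None or r not in by_pos:
                continue
            if q in aln.masked_read_positions or b not in VALID_BASES:
                continue
            for site in by_pos[r]:
                overlaps[site.group] += 1
                if b == site.diagnostic_base:
                    matches[site.group] += 1
    groups = sorted({s.group for s in sites})
    return [SupportTally(g, matches[g], overlaps[g]) for g in groups]


@dataclass(frozen=True)
class ConsensusCall:
    ref_position: int
    base: str  # A/C/G/T or N
    coverage: int
    majority_fraction: Optional[Fraction]


def call_consensus(
    alignments: Sequence[AlignedFragment],
    reference_length: int,
    min_coverage: int = 2,
    majority_fraction: Fraction = Fraction(2, 3),
) -> tuple[list[ConsensusCall], str]:
    """Majority-vote partial consensus over masked alignments.

    A base is called at a reference position iff at least ``min_coverage``
    unmasked fragments cover it and the modal base's fraction is at least
    ``majority_fraction`` (compared as exact rationals, so 2 of 3
    fragments meet the two-thirds default).  Ties for the mode, thin
    coverage, or insufficient majority yield N.  Returns per-position
    calls (positions with any coverage) and the full N-padded consensus
    string of ``reference_length`` characters.
    """
    majority_fraction = Fraction(majority_fraction)
    counts: dict[int, Counter[str]] = defaultdict(Counter)
    for aln in alignments:
        for r, q, b in aln.pairs:
            if r is None or q is None:
                continue
            if q in aln.masked_read_positions or b not in VALID_BASES:
                continue
            counts[r][b] += 1
    calls: list[ConsensusCall] = []
    seq = ["N"] * reference_length
    for pos in sorted(counts):
        tally = counts[pos]
        cov = sum(tally.values())
        top = tally.most_common()
        base = "N"
        frac: Optional[Fraction] = None
        if cov >= min_coverage:
            best_count = top[0][1]
            leaders = [b for b, c in top if c == best_count]
            frac = Fraction(best_count, cov)
            if len(leaders) == 1 and frac >= majority_fraction:
                base = leaders[0]
        calls.append(ConsensusCall(pos, base, cov, frac))
        if 0 <= pos < reference_length:
            seq[pos] = base
    return calls, "".join(seq)


def consensus_to_table(calls: Sequence[ConsensusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_position": c.ref_position,
                "base": c.base,
                "coverage": c.coverage,
                "majority_fraction": float(c.majority_fraction)
                if c.majority_fraction is not None
                else float("nan"),
            }
            for c in calls
        ],
        columns=["ref_position", "base", "coverage", "majority_fraction"],
    )
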