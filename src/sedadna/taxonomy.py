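"""Family-level taxonomic binning of fragments by lowest common ancestor.

Short fragments rarely identify a species: a fragment matching several
cervid mitogenomes equally well is only safely assigned to the deepest
taxon ancestral to all of its hits.  This module implements that
lowest-common-ancestor assignment over a user-supplied taxonomy, the
family-presence thresholds (a family counts as present given at least
three fragments and at least 1% of identifiable fragments), and a
desk-scale semi-global matcher over a mitogenome panel that produces the
per-fragment hit lists.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import pandas as pd

from .fragments import AlignedFragment, Fragment, revcomp

RANKS = ("species", "genus", "family", "above-family")
ROOT_MARKERS = {"", "root", "-", None}


@dataclass(frozen=True)
class TaxonomyNode:
    taxon_id: str
    parent_id: Optional[str]
    rank: str
    name: str = ""


@dataclass(frozen=True)
class HitRecord:
    """One fragment-to-reference match (a BLAST-hit stand-in)."""

    fragment_id: str
    reference_id: str
    taxon_id: str
    score: int  # edit distance (lower is better)


@dataclass(frozen=True)
class FamilyAssignment:
    fragment_id: str
    lca_taxon_id: str
    family_id: Optional[str]
    identifiable: bool


class Taxonomy:
    """A rooted taxonomy with parent-chain navigation.

    Every node's parent chain must terminate at the single root (a node
    whose parent is itself, empty, or a root marker).
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[str, TaxonomyNode] = {}
        for n in nodes:
            if n.taxon_id in self.nodes:
                raise ValueError(f"duplicate taxon id {n.taxon_id!r}")
            self.nodes[n.taxon_id] = n
        # a marker string only denotes the root when no node carries it as id
        roots = [
            t for t, n in self.nodes.items()
            if n.parent_id == t
            or (n.parent_id in ROOT_MARKERS and n.parent_id not in self.nodes)
        ]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        self._depth: dict[str, int] = {}

    def parent(self, taxon_id: str) -> Optional[str]:
        n = self.nodes[taxon_id]
        if taxon_id == self.root:
            return None
        return n.parent_id

    def depth(self, taxon_id: str) -> int:
        d = self._depth.get(taxon_id)
        if d is None:
            p = self.parent(taxon_id)
            d = 0 if p is None else self.depth(p) + 1
            self._depth[taxon_id] = d
        return d

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Node ids from ``taxon_id`` up to and including the root."""
        if taxon_id not in self.nodes:
            raise KeyError(f"taxon {taxon_id!r} not in taxonomy")
        path = [taxon_id]
        seen = {taxon_id}
        while (p := self.parent(path[-1])) is not None:
            if p in seen:
                raise ValueError(f"cycle in taxonomy at {p!r}")
            path.append(p)
            seen.add(p)
        return path

    def lca(self, taxon_ids: Sequence[str]) -> str:
        """Lowest common ancestor by depth-equalising parent walks."""
        if not taxon_ids:
            raise ValueError("lca of empty taxon set")
        ids = list(dict.fromkeys(taxon_ids))
        cur = ids[0]
        if cur not in self.nodes:
            raise KeyError(f"taxon {cur!r} not in taxonomy")
        for other in ids[1:]:
            if other not in self.nodes:
                raise KeyError(f"taxon {other!r} not in taxonomy")
            a, b = cur, other
            while self.depth(a) > self.depth(b):
                a = self.parent(a)
            while self.depth(b) > self.depth(a):
                b = self.parent(b)
            while a != b:
                a = self.parent(a)
                b = self.parent(b)
            cur = a
        return cur

    def family_of(self, taxon_id: str) -> Optional[str]:
        """The family-rank ancestor of ``taxon_id`` (itself included)."""
        for t in self.path_to_root(taxon_id):
            if self.nodes[t].rank == "family":
                return t
        return None

    def at_or_below_family(self, taxon_id: str) -> bool:
        return self.nodes[taxon_id].rank in ("species", "genus", "family")


def read_taxonomy_tsv(path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"taxon_id", "parent_id", "rank", "name"}
    if not required.issubset(df.columns):
        raise ValueError(f"taxonomy table must have columns {sorted(required)}")
    return Taxonomy(
        TaxonomyNode(r.taxon_id, r.parent_id, r.rank, r.name)
        for r in df.itertuples()
    )


def write_taxonomy_tsv(tax: Taxonomy, path) -> None:
    pd.DataFrame(
        [
            {"taxon_id": n.taxon_id, "parent_id": n.parent_id or "",
             "rank": n.rank, "name": n.name}
            for n in tax.nodes.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def match_to_panel(
    fragments: Sequence[Fragment],
    panel: Sequence[tuple[str, str, str]],
    max_edit_fraction: float = 0.1,
) -> list[HitRecord]:
    """Match fragments against a mitogenome panel by semi-global alignment.

    For each fragment the best edit distance to every panel sequence is
    computed on both strands (edlib, infix/"HW" mode).  Hits are all
    references within ``floor(max_edit_fraction * len(fragment))`` edits
    and within one edit of the fragment's best hit — a deterministic,
    desk-scale surrogate for a BLAST search against a mitogenome database.

    ``panel`` rows are ``(reference_id, sequence, taxon_id)``.
    """
    if not panel:
        raise ValueError("empty reference panel")
    hits: list[HitRecord] = []
    for frag in fragments:
        k = int(max_edit_fraction * len(frag.sequence))
        fwd, rev = frag.sequence, revcomp(frag.sequence)
        dists: list[tuple[str, str, int]] = []
        for ref_id, ref_seq, taxon_id in panel:
            d = min(
                edlib.align(fwd, ref_seq, mode="HW", task="distance", k=k)["editDistance"],
                edlib.align(rev, ref_seq, mode="HW", task="distance", k=k)["editDistance"],
                key=lambda x: x if x >= 0 else 10 ** 9,
            )
            if d >= 0:
                dists.append((ref_id, taxon_id, d))
        if not dists:
            continue
        best = min(d for _, _, d in dists)
        hits.extend(
            HitRecord(frag.id, ref_id, taxon_id, d)
            for ref_id, taxon_id, d in dists
            if d <= best + 1
        )
    return hits


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _edlib_pairs(cigar: str, ref_start: int, sam_seq: str):
    """Alignment columns from an edlib path cigar ('=XID', query-first)."""
    pairs = []
    r, q = ref_start, 0
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        for _ in range(n):
            if op in "=XM":
                pairs.append((r, q, sam_seq[q]))
                r += 1
                q += 1
            elif op == "I":  # consumes query only: insertion to the reference
                pairs.append((None, q, sam_seq[q]))
                q += 1
            else:  # D consumes reference only
                pairs.append((r, None, None))
                r += 1
    return pairs, r


def align_to_reference(
    fragments: Sequence[Fragment],
    reference_id: str,
    reference_seq: str,
    max_edit_fraction: float = 0.1,
) -> list[AlignedFragment]:
    """Desk-scale re-alignment of fragments to one representative genome.

    Each fragment is aligned semi-globally (edlib, both strands) to the
    reference; the better strand wins, ties going to forward.  Fragments
    beyond ``floor(max_edit_fraction * length)`` edits are dropped.
    Among equal-cost placements the longest reference span is taken
    (substitutions preferred over terminal indels, as a damaged terminal
    base should stay an aligned mismatch) and the path is recomputed
    globally within that window.  Mapping quality is 37 for a unique best
    placement and 0 when an equally good placement exists elsewhere or on
    the other strand — mirroring how short-read mappers zero out
    ambiguous placements.
    """
    out = []
    for frag in fragments:
        k = int(max_edit_fraction * len(frag.sequence))
        candidates = []
        for strand, q in (("+", frag.sequence), ("-", revcomp(frag.sequence))):
            res = edlib.align(q, reference_seq, mode="HW", task="path", k=k)
            if res["editDistance"] >= 0:
                candidates.append((res["editDistance"], strand, q, res))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1]))
        dist, strand, sam_seq, res = candidates[0]
        locs = res["locations"]
        s, e = max(locs, key=lambda se: (se[1] - se[0], -se[0]))
        # only a placement away from the chosen window counts as ambiguous;
        # overlapping locations are alternative paths of the same placement
        ambiguous = any(le < s or ls > e for ls, le in locs) or (
            len(candidates) > 1 and candidates[1][0] == dist
        )
        start = s
        window = reference_seq[s : e + 1]
        res_nw = edlib.align(sam_seq, window, mode="NW", task="path")
        pairs, ref_end = _edlib_pairs(res_nw["cigar"], start, sam_seq)
        out.append(
            AlignedFragment(
                fragment_id=frag.id,
                reference_id=reference_id,
                ref_start=start,
                ref_end=ref_end,
                strand=strand,
                mapping_quality=0 if ambiguous else 37,
                pairs=pairs,
                library_id=frag.library_id,
            )
        )
    return out


def lca_assign(
    hits: Sequence[HitRecord], taxonomy: Taxonomy
) -> list[FamilyAssignment]:
    """Assign each fragment to the LCA of its hit taxa, retained at family level.

    A fragment is *identifiable* iff its LCA sits at or below family rank;
    its ``family_id`` is then the family-rank ancestor of the LCA.

    Raises
    ------
    KeyError
        If a hit references a taxon absent from the taxonomy.
    """
    by_fragment: dict[str, list[str]] = defaultdict(list)
    order: list[str] = []
    for h in hits:
        if h.fragment_id not in by_fragment:
            order.append(h.fragment_id)
        by_fragment[h.fragment_id].append(h.taxon_id)
    out = []
    for fid in order:
        lca = taxonomy.lca(by_fragment[fid])
        identifiable = taxonomy.at_or_below_family(lca)
        family = taxonomy.family_of(lca) if identifiable else None
        out.append(FamilyAssignment(fid, lca, family, identifiable))
    return out


def family_presence(
    assignments: Sequence[FamilyAssignment],
    min_family_fragments: int = 3,
    min_family_pct: float = 1.0,
) -> pd.DataFrame:
    """Apply the family-presence thresholds.

    A family is called present iff at least ``min_family_fragments``
    fragments AND at least ``min_family_pct`` percent of identifiable
    fragments (those with an LCA at or below family rank) were assigned
    to it.  Returns a table with columns family_id, n_fragments,
    pct_identifiable, present.
    """
    n_identifiable = sum(a.identifiable for a in assignments)
    counts: dict[str, int] = defaultdict(int)
    for a in assignments:
        if a.family_id is not None:
            counts[a.family_id] += 1
    if n_identifiable == 0 and len(assignments) > 0:
        warnings.warn("no identifiable fragments; all families absent")
    rows = []
    for fam in sorted(counts):
        n = counts[fam]
        pct = 100.0 * n / n_identifiable if n_identifiable else 0.0
        rows.append(
            {
                "family_id": fam,
                "n_fragments": n,
                "pct_identifiable": pct,
                "present": n >= min_family_fragments and pct >= min_family_pct,
            }
        )
    return pd.DataFrame(rows, columns=["family_id", "n_fragments", "pct_identifiable", "present"])
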