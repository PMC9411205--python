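"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Bio.SeqIO; SAM through pysam; tabular interchange
(index tables, taxonomy, hit lists, reports) through pandas TSV.  Fragment
multiplicity survives FASTA/FASTQ round-trips via a ``;mult=N`` suffix on
the record id.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragments import AlignedFragment, Fragment, IndexPair

_MULT_RE = re.compile(r";mult=(\d+)$")


def _to_record(frag: Fragment) -> SeqRecord:
    rid = frag.id
    if frag.multiplicity > 1:
        rid = f"{rid};mult={frag.multiplicity}"
    return SeqRecord(Seq(frag.sequence), id=rid, description="")


def _from_record(rec: SeqRecord, library_id: str, sample_id: str) -> Fragment:
    rid = rec.id
    mult = 1
    m = _MULT_RE.search(rid)
    if m:
        mult = int(m.group(1))
        rid = rid[: m.start()]
    return Fragment(
        id=rid,
        sequence=str(rec.seq).upper(),
        multiplicity=mult,
        library_id=library_id,
        sample_id=sample_id,
    )


def read_fasta_fragments(path, library_id: str = "", sample_id: str = "") -> list[Fragment]:
    return [_from_record(r, library_id, sample_id) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta_fragments(fragments: Iterable[Fragment], path) -> None:
    SeqIO.write((_to_record(f) for f in fragments), str(path), "fasta")


def read_fastq_fragments(path, library_id: str = "", sample_id: str = "") -> list[Fragment]:
    return [_from_record(r, library_id, sample_id) for r in SeqIO.parse(str(path), "fastq")]


def write_fastq_fragments(
    fragments: Iterable[Fragment], path, quality_char: str = "I"
) -> None:
    q = ord(quality_char) - 33
    recs = []
    for f in fragments:
        rec = _to_record(f)
        rec.letter_annotations["phred_quality"] = [q] * len(f.sequence)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_reference_fasta(path) -> dict[str, str]:
    """Reference sequences keyed by record id (description dropped)."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_reference_fasta(references: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in references.items()),
        str(path),
        "fasta",
    )


# -- index tables ------------------------------------------------------------

def read_index_table(path) -> list[IndexPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "i7", "i5"}
    if not required.issubset(df.columns):
        raise ValueError(f"index table must have columns {sorted(required)}")
    return [
        IndexPair(i7=row.i7, i5=row.i5, library_id=row.library_id)
        for row in df.itertuples()
    ]


def write_index_table(pairs: Sequence[IndexPair], path) -> None:
    pd.DataFrame(
        {"library_id": [p.library_id for p in pairs],
         "i7": [p.i7 for p in pairs],
         "i5": [p.i5 for p in pairs]}
    ).to_csv(path, sep="\t", index=False)


# -- SAM ---------------------------------------------------------------------

def _pairs_to_cigar(pairs) -> list[tuple[int, int]]:
    """CIGAR ops (pysam codes: 0=M, 1=I, 2=D) from alignment columns."""
    ops: list[tuple[int, int]] = []
    for r, q, _ in pairs:
        if r is not None and q is not None:
            op = 0
        elif q is not None:
            op = 1
        else:
            op = 2
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return ops


def read_sam(path) -> list[AlignedFragment]:
    """Parse mapped records of a SAM file into :class:`AlignedFragment`.

    pysam converts SAM's 1-based inclusive coordinates to 0-based half-open
    at this boundary.  Read bases are stored reference-forward (SAM SEQ
    orientation).  The library is taken from the read group's LB field when
    a matching ``@RG`` header line exists.
    """
    out: list[AlignedFragment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        rg_lib = {
            rg.get("ID"): rg.get("LB", "")
            for rg in sam.header.to_dict().get("RG", [])
        }
        for read in sam:
            if read.is_unmapped:
                continue
            seq = read.query_sequence or ""
            pairs = [
                (rpos, qpos, seq[qpos] if qpos is not None else None)
                for qpos, rpos in read.get_aligned_pairs()
            ]
            lib = ""
            if read.has_tag("RG"):
                lib = rg_lib.get(read.get_tag("RG"), "")
            out.append(
                AlignedFragment(
                    fragment_id=read.query_name,
                    reference_id=read.reference_name,
                    ref_start=read.reference_start,
                    ref_end=read.reference_end,
                    strand="-" if read.is_reverse else "+",
                    mapping_quality=read.mapping_quality,
                    pairs=pairs,
                    library_id=lib,
                )
            )
    return out


def write_sam(
    alignments: Sequence[AlignedFragment],
    reference_lengths: dict[str, int],
    path,
    libraries: Optional[dict[str, str]] = None,
) -> None:
    """Write alignments as SAM (plain text, with @SQ header lines).

    ``libraries`` optionally maps read-group ids to library names, emitted
    as ``@RG`` lines; alignments carrying a ``library_id`` reference them
    via the RG tag.
    """
    refs = list(reference_lengths)
    header: dict = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r, "LN": reference_lengths[r]} for r in refs],
    }
    if libraries:
        header["RG"] = [{"ID": k, "LB": v} for k, v in libraries.items()]
    ref_index = {r: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for aln in alignments:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = aln.fragment_id
            a.query_sequence = aln.query_sequence()
            a.flag = 16 if aln.strand == "-" else 0
            a.reference_id = ref_index[aln.reference_id]
            a.reference_start = aln.ref_start
            a.mapping_quality = aln.mapping_quality
            a.cigar = _pairs_to_cigar(aln.pairs)
            a.query_qualities = pysam.qualitystring_to_array("I" * len(a.query_sequence))
            if aln.library_id:
                a.set_tag("RG", aln.library_id)
            sam.write(a)


# -- hit tables and taxonomy -------------------------------------------------

HIT_COLUMNS = ["fragment_id", "reference_id", "taxon_id", "score"]


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"fragment_id": str, "reference_id": str,
                                            "taxon_id": str})
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns {sorted(missing)}")
    return df[HIT_COLUMNS]


def write_hit_table(df: pd.DataFrame, path) -> None:
    df[HIT_COLUMNS].to_csv(path, sep="\t", index=False)
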