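"""End-to-end orchestration: from reads to the screening report and the
placement outputs.

``run_screening`` chains the stages of the sediment-DNA screening:
optional demultiplexing, length filtering, PCR-duplicate collapse,
family-level taxonomic binning, per-family re-alignment, mapping-quality
filtering, damage profiling, and ancientness authentication — producing a
per-library x per-family report (one :class:`FamilyScreenRecord` row).
``run_placement`` takes an authenticated alignment set plus a grouped
mitogenome MSA and produces informative-site catalogues, per-group
support tallies and a partial consensus genome.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import seqio
from .damage import authenticate, filter_mq, substitution_profile
from .fragments import (
    AlignedFragment,
    DemuxResult,
    Fragment,
    PipelineParams,
    collapse_duplicates,
    demultiplex,
    filter_length,
)
from .placement import (
    GroupedMSA,
    call_consensus,
    consensus_to_table,
    find_informative_sites,
    mask_damage,
    parse_groups,
    sites_to_table,
    tally_support,
)
from .taxonomy import (
    HitRecord,
    align_to_reference,
    family_presence,
    lca_assign,
    match_to_panel,
    read_taxonomy_tsv,
)

log = logging.getLogger("sedadna")

REPORT_COLUMNS = [
    "sample_id", "library_id", "layer", "family", "n_assigned",
    "pct_identifiable", "k5", "n5", "k3", "n3", "f5", "f3", "p5", "p3",
    "present", "ancient",
]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str = "out"
    seed: int = 0
    sample_id: str = ""
    layer: str = ""
    params: PipelineParams = field(default_factory=PipelineParams)
    # screening inputs: either per-library reads, or raw reads + index table
    reads: dict[str, str] = field(default_factory=dict)  # library -> FASTA/FASTQ
    raw_reads_tsv: Optional[str] = None  # columns: id, sequence, i7, i5
    index_table: Optional[str] = None
    panel_fasta: Optional[str] = None  # headers: ">ref_id taxon=<taxon_id>"
    taxonomy_tsv: Optional[str] = None
    hit_tables: dict[str, str] = field(default_factory=dict)  # library -> TSV
    family_references: dict[str, str] = field(default_factory=dict)  # family -> FASTA
    max_edit_fraction: float = 0.1
    dedup_before_length_filter: bool = False
    include_zero_rows: bool = False
    # placement inputs
    msa_fasta: Optional[str] = None
    msa_reference: Optional[str] = None
    group_rule: str = "genus_token"
    group_table: Optional[str] = None
    alignments_sam: Optional[str] = None
    site_mode: str = "strict"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "params" in doc and doc["params"] is not None:
            pknown = {f.name for f in dataclasses.fields(PipelineParams)}
            punknown = set(doc["params"]) - pknown
            if punknown:
                raise ValueError(f"unknown params keys: {sorted(punknown)}")
            doc["params"] = PipelineParams(**doc["params"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["params"]["majority_fraction"] = str(doc["params"]["majority_fraction"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def _load_panel(path) -> list[tuple[str, str, str]]:
    """Panel FASTA rows (reference_id, sequence, taxon_id); the taxon comes
    from a ``taxon=<id>`` key in the record description."""
    from Bio import SeqIO

    panel = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = None
        for token in rec.description.split():
            if token.startswith("taxon="):
                taxon = token[len("taxon="):]
        if taxon is None:
            raise ValueError(f"panel record {rec.id!r} lacks a taxon= key")
        panel.append((rec.id, str(rec.seq).upper(), taxon))
    return panel


def _load_library_reads(config: RunConfig) -> tuple[dict[str, list[Fragment]], int]:
    """Reads per library, demultiplexing when raw reads are supplied."""
    if config.raw_reads_tsv:
        if not config.index_table:
            raise ValueError("raw_reads_tsv requires index_table")
        df = pd.read_csv(config.raw_reads_tsv, sep="\t", dtype=str)
        raw = list(df[["id", "sequence", "i7", "i5"]].itertuples(index=False, name=None))
        result: DemuxResult = demultiplex(raw, seqio.read_index_table(config.index_table))
        return result.by_library, result.n_discarded
    by_library = {}
    for lib, path in config.reads.items():
        reader = (
            seqio.read_fastq_fragments
            if str(path).endswith((".fastq", ".fq"))
            else seqio.read_fasta_fragments
        )
        by_library[lib] = reader(path, library_id=lib, sample_id=config.sample_id)
    return by_library, 0


def screen_library(
    fragments: list[Fragment],
    panel: list[tuple[str, str, str]],
    taxonomy,
    params: PipelineParams,
    family_refs: dict[str, tuple[str, str]],
    max_edit_fraction: float = 0.1,
    hits: Optional[list[HitRecord]] = None,
    dedup_before_length_filter: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Screen one library's fragments; returns (report rows, stage counts).

    ``family_refs`` maps family id to ``(reference_id, sequence)`` used
    for re-alignment and damage profiling.
    """
    counts = {"raw": len(fragments)}
    if dedup_before_length_filter:
        deduped = collapse_duplicates(
            fragments, "sequence", min_multiplicity=params.min_multiplicity
        )
        kept = filter_length(deduped, params.min_length)
        counts["deduped"] = len(deduped)
        counts["length_ok"] = len(kept)
    else:
        long_enough = filter_length(fragments, params.min_length)
        kept = collapse_duplicates(
            long_enough, "sequence", min_multiplicity=params.min_multiplicity
        )
        counts["length_ok"] = len(long_enough)
        counts["deduped"] = len(kept)

    # each stage can only discard fragments
    if dedup_before_length_filter:
        assert counts["length_ok"] <= counts["deduped"] <= counts["raw"]
    else:
        assert counts["deduped"] <= counts["length_ok"] <= counts["raw"]
    if hits is None:
        hits = match_to_panel(kept, panel, max_edit_fraction)
    assignments = lca_assign(hits, taxonomy)
    counts["assigned"] = sum(a.identifiable for a in assignments)
    presence = family_presence(
        assignments, params.min_family_fragments, params.min_family_pct
    )

    frag_by_id = {f.id: f for f in kept}
    rows = []
    for rec in presence.itertuples():
        fam = rec.family_id
        fam_fragments = [
            frag_by_id[a.fragment_id]
            for a in assignments
            if a.family_id == fam and a.fragment_id in frag_by_id
        ]
        row = {
            "family": fam,
            "n_assigned": rec.n_fragments,
            "pct_identifiable": rec.pct_identifiable,
            "present": rec.present,
            "k5": math.nan, "n5": math.nan, "k3": math.nan, "n3": math.nan,
            "f5": math.nan, "f3": math.nan, "p5": math.nan, "p3": math.nan,
            "ancient": "not_assessable",
        }
        if fam in family_refs and fam_fragments:
            ref_id, ref_seq = family_refs[fam]
            aligned = align_to_reference(
                fam_fragments, ref_id, ref_seq, max_edit_fraction
            )
            aligned = filter_mq(aligned, params.min_mq)
            profile = substitution_profile(
                aligned, ref_seq, params.profile_window, reference_id=ref_id
            )
            auth = authenticate(
                profile, params.damage_null_rate, params.alpha, taxon=fam
            )
            row.update(
                k5=auth.k5, n5=auth.n5, k3=auth.k3, n3=auth.n3,
                f5=auth.f5, f3=auth.f3,
                p5=auth.p5 if auth.p5 is not None else math.nan,
                p3=auth.p3 if auth.p3 is not None else math.nan,
                ancient=auth.ancient,
            )
            # an "ancient" verdict is only meaningful for present families
            if auth.ancient == "yes" and not rec.present:
                row["ancient"] = "no"
        rows.append(row)
    columns = [c for c in REPORT_COLUMNS if c not in ("sample_id", "library_id", "layer")]
    return pd.DataFrame(rows, columns=columns), counts


def run_screening(config: RunConfig) -> pd.DataFrame:
    """Execute the full screening pipeline and write the report.

    Returns the report as a DataFrame (columns per
    :data:`REPORT_COLUMNS`); all per-stage artifacts and a resolved copy
    of the configuration are written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")

    if not config.panel_fasta or not config.taxonomy_tsv:
        raise ValueError("screening requires panel_fasta and taxonomy_tsv")
    panel = _load_panel(config.panel_fasta)
    taxonomy = read_taxonomy_tsv(config.taxonomy_tsv)

    # family -> representative reference for re-alignment: explicit mapping
    # wins; otherwise the first panel member of each family stands in.
    family_refs: dict[str, tuple[str, str]] = {}
    for fam, path in config.family_references.items():
        refs = seqio.read_reference_fasta(path)
        rid, rseq = next(iter(refs.items()))
        family_refs[fam] = (rid, rseq)
    for ref_id, seq, taxon in panel:
        fam = taxonomy.family_of(taxon)
        if fam is not None and fam not in family_refs:
            family_refs[fam] = (ref_id, seq)

    by_library, n_discarded = _load_library_reads(config)
    log.info("demux: %d libraries, %d reads discarded", len(by_library), n_discarded)

    all_rows = []
    for lib in sorted(by_library):
        hits = None
        if lib in config.hit_tables:
            df = seqio.read_hit_table(config.hit_tables[lib])
            hits = [
                HitRecord(r.fragment_id, r.reference_id, r.taxon_id, int(r.score))
                for r in df.itertuples()
            ]
        report, counts = screen_library(
            by_library[lib], panel, taxonomy, config.params, family_refs,
            config.max_edit_fraction, hits=hits,
            dedup_before_length_filter=config.dedup_before_length_filter,
        )
        log.info("library %s: %s", lib, " ".join(f"{k}={v}" for k, v in counts.items()))
        report.insert(0, "layer", config.layer)
        report.insert(0, "library_id", lib)
        report.insert(0, "sample_id", config.sample_id)
        all_rows.append(report)

    if all_rows:
        report = pd.concat(all_rows, ignore_index=True)
        if not config.include_zero_rows:
            report = report[report["n_assigned"] > 0].reset_index(drop=True)
    else:
        report = pd.DataFrame(columns=REPORT_COLUMNS)
    report = report.reindex(columns=REPORT_COLUMNS)
    write_report(report, outdir / "screening_report.tsv")
    return report


def write_report(report: pd.DataFrame, path) -> None:
    """Write the screening report TSV; missing values as NA, floats fixed
    to 6 significant digits so identical runs are byte-identical."""
    report.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


@dataclass
class PlacementResult:
    sites_strict: pd.DataFrame
    sites_frequency: pd.DataFrame
    support: pd.DataFrame
    consensus_calls: pd.DataFrame
    consensus_sequence: str


def run_placement(
    config: RunConfig,
    alignments: Optional[list[AlignedFragment]] = None,
    msa: Optional[GroupedMSA] = None,
) -> PlacementResult:
    """Informative sites (both modes), support tallies and consensus.

    ``alignments``/``msa`` may be passed in memory; otherwise they are
    loaded from ``config.alignments_sam`` and ``config.msa_fasta``.
    Support tallies use the sites of ``config.site_mode``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params

    if msa is None:
        if not config.msa_fasta or not config.msa_reference:
            raise ValueError("placement requires msa_fasta and msa_reference")
        msa = load_grouped_msa(
            config.msa_fasta, config.msa_reference,
            rule=config.group_rule, group_table=config.group_table,
        )
    if alignments is None:
        if not config.alignments_sam:
            raise ValueError("placement requires alignments (SAM or in-memory)")
        alignments = seqio.read_sam(config.alignments_sam)

    strict = find_informative_sites(msa, "strict")
    freq = find_informative_sites(msa, "frequency", params.group_fixed_fraction)
    masked = [mask_damage(a, params.mask_terminal) for a in alignments]
    ref_len = len(msa.reference_row().replace("-", ""))
    sites = strict if config.site_mode == "strict" else freq
    support = tally_support(masked, sites, reference_length=ref_len)
    calls, consensus = call_consensus(
        masked, ref_len, params.min_coverage, params.majority_fraction
    )

    sites_to_table(strict).to_csv(outdir / "sites_strict.tsv", sep="\t", index=False)
    sites_to_table(freq).to_csv(outdir / "sites_frequency.tsv", sep="\t", index=False)
    support_df = pd.DataFrame(
        [{"group": t.group, "matches": t.matches, "overlaps": t.overlaps} for t in support],
        columns=["group", "matches", "overlaps"],
    )
    support_df.to_csv(outdir / "support.tsv", sep="\t", index=False)
    calls_df = consensus_to_table(calls)
    calls_df.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    seqio.write_reference_fasta({"consensus": consensus}, outdir / "consensus.fasta")
    return PlacementResult(
        sites_strict=sites_to_table(strict),
        sites_frequency=sites_to_table(freq),
        support=support_df,
        consensus_calls=calls_df,
        consensus_sequence=consensus,
    )


def load_grouped_msa(
    path, reference_id: str, rule: str = "genus_token", group_table=None
) -> GroupedMSA:
    """Read an aligned FASTA into a :class:`GroupedMSA`.

    Sequence *names* are the full FASTA descriptions (accession plus
    organism), which the genus-token rule needs; ``reference_id`` may be
    either the accession or the full description.  ``group_table`` is a
    path to a two-column TSV (name_or_accession, group) for the
    mapping-table rule.
    """
    from Bio import SeqIO

    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.description)
        rows.append(str(rec.seq).upper())
    mapping = None
    if group_table is not None:
        df = pd.read_csv(group_table, sep="\t", dtype=str, header=None,
                         names=["name", "group"])
        mapping = dict(zip(df["name"], df["group"]))
        rule = "mapping_table"
    groups = parse_groups(names, rule=rule, mapping_table=mapping)
    ref = reference_id
    if ref not in names:
        by_acc = {n.split()[0]: n for n in names}
        if ref in by_acc:
            ref = by_acc[ref]
        else:
            raise ValueError(f"reference {reference_id!r} not found in MSA")
    return GroupedMSA(names=names, rows=rows, reference_id=ref, groups=groups)
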