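"""Self-contained synthetic datasets exercising the whole pipeline.

Builders that write a complete, internally consistent screening or
placement input set (references, panel, taxonomy, reads, config) from the
simulator — a deer-like ancient component plus a modern bovid-like
contaminant — so the end-to-end pipeline can be run and checked against
ground truth anywhere, with no external data.  All sequences are
simulator-generated stand-ins for real mitogenomes.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from . import seqio
from .fragments import Fragment
from .pipeline import RunConfig
from .placement import GroupedMSA
from .simulate import SimParams, SimResult, generate_reference, simulate_fragments
from .taxonomy import Taxonomy, TaxonomyNode, write_taxonomy_tsv

# minimal mammal taxonomy covering the two simulated families
TAXONOMY_ROWS = [
    ("Mammalia", "", "above-family", "Mammalia"),
    ("Artiodactyla", "Mammalia", "above-family", "Artiodactyla"),
    ("Cervidae", "Artiodactyla", "family", "Cervidae"),
    ("Bovidae", "Artiodactyla", "family", "Bovidae"),
    ("Cervus", "Cervidae", "genus", "Cervus"),
    ("Bos", "Bovidae", "genus", "Bos"),
    ("Cervus_elaphus", "Cervus", "species", "Cervus elaphus"),
    ("Bos_taurus", "Bos", "species", "Bos taurus"),
]


def demo_taxonomy() -> Taxonomy:
    return Taxonomy(TaxonomyNode(*row) for row in TAXONOMY_ROWS)


def synthetic_screening_dataset(
    outdir,
    seed: int = 0,
    n_endogenous: int = 300,
    n_contaminant: int = 100,
    reference_length: int = 12000,
    d_max: float = 0.4,
) -> tuple[RunConfig, SimResult]:
    """Write a full screening input set under ``outdir``.

    ``n_endogenous`` damaged deer-like reads and ``n_contaminant``
    undamaged bovid-like reads (expected counts; the split is Bernoulli)
    are pooled into one library.  The duplication rate is set high
    (``dup_mean = 2``) because the seen-at-least-twice duplicate filter
    presumes sequencing deep enough that most genuine molecules are
    observed repeatedly — the regime the screening strategy is built for.
    Returns the ready-to-run :class:`RunConfig` plus the simulation with
    its ground truth.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    refs = {
        "cerv_ref": generate_reference(reference_length, 0.4, seed * 13 + 1),
        "bos_ref": generate_reference(reference_length, 0.4, seed * 13 + 2),
    }
    n_total = n_endogenous + n_contaminant
    params = SimParams(
        seed=seed * 13 + 3,
        n_fragments=n_total,
        d_max=d_max,
        contam_fraction=n_contaminant / n_total,
        contam_reference="bos_ref",
        taxon_mix={"cerv_ref": 1.0},
        dup_mean=2.0,
        library_id="L1",
    )
    sim = simulate_fragments(params, refs)
    seqio.write_fasta_fragments(sim.fragments, out / "reads.fasta")
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    with open(out / "panel.fasta", "w") as fh:
        fh.write(f">cerv_ref taxon=Cervus_elaphus\n{refs['cerv_ref']}\n")
        fh.write(f">bos_ref taxon=Bos_taurus\n{refs['bos_ref']}\n")
    write_taxonomy_tsv(demo_taxonomy(), out / "taxonomy.tsv")

    config = RunConfig(
        outdir=str(out / "results"),
        seed=seed,
        sample_id="SYN1",
        layer="synthetic",
        reads={"L1": str(out / "reads.fasta")},
        panel_fasta=str(out / "panel.fasta"),
        taxonomy_tsv=str(out / "taxonomy.tsv"),
    )
    config.to_yaml(out / "config.yaml")
    return config, sim


def _mutate(seq: str, positions: list[int], seed: int) -> str:
    """Substitute a deterministic different base at each given position."""
    import numpy as np

    rng = np.random.default_rng(seed)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return "".join(out)


def synthetic_placement_dataset(
    seed: int = 0,
    reference_length: int = 4000,
    n_reads: int = 600,
    divergence_step: int = 40,
    d_max: float = 0.4,
) -> tuple[GroupedMSA, SimResult, dict[str, str]]:
    """Two diverged genus groups plus reads simulated from one of them.

    Builds a gapless four-genome MSA: two "Cervus-like" genomes (the
    simulated source lineage) and two "Dama-like" genomes carrying shared
    derived substitutions every ``divergence_step`` bp, plus a few private
    mutations per genome so neither group is artificially uniform.  Reads
    are simulated from the Cervus-like reference, so the ground truth of
    every support tally and consensus call is known.  Returns the MSA, the
    simulation, and the reference sequences by name.
    """
    base = generate_reference(reference_length, 0.4, seed * 17 + 5)
    shared_derived = list(range(20, reference_length - 20, divergence_step))
    dama_base = _mutate(base, shared_derived, seed * 17 + 6)
    # private mutations: small, non-overlapping with the shared set
    priv = [p + 11 for p in shared_derived[::7]]
    cervus_a = base
    cervus_b = _mutate(base, priv, seed * 17 + 7)
    dama_a = dama_base
    dama_b = _mutate(dama_base, [p + 23 for p in shared_derived[::9]], seed * 17 + 8)

    names = [
        "CV001 Cervus elaphus synthetic",
        "CV002 Cervus nippon synthetic",
        "DM001 Dama dama synthetic",
        "DM002 Dama mesopotamica synthetic",
    ]
    msa = GroupedMSA(
        names=names,
        rows=[cervus_a, cervus_b, dama_a, dama_b],
        reference_id=names[0],
        groups={n: n.split()[1] for n in names},
    )
    params = SimParams(
        seed=seed * 17 + 9,
        n_fragments=n_reads,
        d_max=d_max,
        contam_fraction=0.0,
        taxon_mix={"cerv_ref": 1.0},
        library_id="L1",
    )
    sim = simulate_fragments(params, {"cerv_ref": cervus_a})
    return msa, sim, {"cerv_ref": cervus_a}


def primary_alignments(sim: SimResult, include_contaminant: bool = False):
    """Non-duplicate, non-wrapped alignment records of a simulation."""
    t = sim.truth
    mask = (t.duplicate_of == "") & ~t.wrapped
    if not include_contaminant:
        mask &= ~t.is_contaminant
    keep = set(t.loc[mask, "read_id"])
    return [
        a for a in sim.alignments
        if a.fragment_id in keep and not a.fragment_id.endswith("/wrap")
    ]
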