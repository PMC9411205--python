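"""Shared fixtures: a small mammal taxonomy, alignment builders, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from sedadna.fragments import AlignedFragment
from sedadna.taxonomy import Taxonomy, TaxonomyNode


def make_alignment(
    fragment_id: str,
    ref_start: int,
    sam_seq: str,
    strand: str = "+",
    mapping_quality: int = 37,
    reference_id: str = "ref",
    library_id: str = "",
) -> AlignedFragment:
    """Gapless alignment; ``sam_seq`` is the reference-forward read sequence."""
    pairs = [(ref_start + i, i, b) for i, b in enumerate(sam_seq)]
    return AlignedFragment(
        fragment_id=fragment_id,
        reference_id=reference_id,
        ref_start=ref_start,
        ref_end=ref_start + len(sam_seq),
        strand=strand,
        mapping_quality=mapping_quality,
        pairs=pairs,
        library_id=library_id,
    )


MAMMAL_NODES = [
    ("root", "root", "above-family", "root"),
    ("Mammalia", "root", "above-family", "Mammalia"),
    ("Artiodactyla", "Mammalia", "above-family", "Artiodactyla"),
    ("Carnivora", "Mammalia", "above-family", "Carnivora"),
    ("Cervidae", "Artiodactyla", "family", "Cervidae"),
    ("Bovidae", "Artiodactyla", "family", "Bovidae"),
    ("Hyaenidae", "Carnivora", "family", "Hyaenidae"),
    ("Cervus", "Cervidae", "genus", "Cervus"),
    ("Dama", "Cervidae", "genus", "Dama"),
    ("Bos", "Bovidae", "genus", "Bos"),
    ("Crocuta", "Hyaenidae", "genus", "Crocuta"),
    ("Cervus_elaphus", "Cervus", "species", "Cervus elaphus"),
    ("Dama_dama", "Dama", "species", "Dama dama"),
    ("Bos_taurus", "Bos", "species", "Bos taurus"),
    ("Crocuta_crocuta", "Crocuta", "species", "Crocuta crocuta"),
]


@pytest.fixture
def mammal_taxonomy() -> Taxonomy:
    return Taxonomy(TaxonomyNode(*row) for row in MAMMAL_NODES)


def brute_force_lca(tax: Taxonomy, taxa) -> str:
    """Independent oracle: intersect full ancestor paths, take the deepest."""
    common = None
    for t in taxa:
        anc = set(tax.path_to_root(t))
        common = anc if common is None else common & anc
    return max(common, key=tax.depth)


def random_taxonomy(rng: np.random.Generator, n_nodes: int) -> Taxonomy:
    """A random rooted taxonomy; ranks follow depth so family logic is sane."""
    nodes = [TaxonomyNode("t0", "root", "above-family", "t0")]
    depths = {0: 0}
    for i in range(1, n_nodes):
        parent = int(rng.integers(i))
        depth = depths[parent] + 1
        depths[i] = depth
        rank = ("above-family", "family", "genus", "species")[min(depth, 3)]
        nodes.append(TaxonomyNode(f"t{i}", f"t{parent}", rank, f"t{i}"))
    return Taxonomy(nodes)
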