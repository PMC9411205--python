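"""Informative-site discovery, deamination masking, support and consensus."""

from fractions import Fraction

import numpy as np
import pytest

from sedadna.placement import (
    GroupedMSA,
    call_consensus,
    find_informative_sites,
    mask_damage,
    parse_groups,
    tally_support,
)

from conftest import make_alignment


def toy_msa(rows_by_name, groups, reference_id=None):
    names = list(rows_by_name)
    return GroupedMSA(
        names=names,
        rows=[rows_by_name[n] for n in names],
        reference_id=reference_id or names[0],
        groups=dict(groups),
    )


def brute_force_strict_sites(msa):
    """Exhaustive per-column scan, independent of the implementation."""
    out = set()
    ref_cols = msa.reference_columns()
    groups = sorted({g for g in msa.groups.values() if g != "ungrouped"})
    for col, ref_pos in ref_cols:
        for g in groups:
            ins = [
                r[col].upper() for n, r in zip(msa.names, msa.rows)
                if msa.groups[n] == g and r[col].upper() in "ACGT"
            ]
            outs = [
                r[col].upper() for n, r in zip(msa.names, msa.rows)
                if msa.groups[n] != g and r[col].upper() in "ACGT"
            ]
            if len(ins) < 2 or len(outs) < 2:
                continue
            if len(set(ins)) == 1 and all(b != ins[0] for b in outs):
                out.add((ref_pos, g, ins[0]))
    return out


class TestParseGroups:
    def test_genus_token(self):
        labels = parse_groups(["NC_007704.2 Cervus elaphus", "NC_020670.1 Crocuta crocuta"])
        assert labels["NC_007704.2 Cervus elaphus"] == "Cervus"
        assert labels["NC_020670.1 Crocuta crocuta"] == "Crocuta"

    def test_mapping_table(self):
        table = {"ACC1": "Megaloceros", "ACC2": "Megaloceros"}
        labels = parse_groups(
            ["ACC1 ancient deer", "ACC2"], rule="mapping_table", mapping_table=table
        )
        assert set(labels.values()) == {"Megaloceros"}

    def test_bare_name_ungrouped_with_warning(self):
        with pytest.warns(UserWarning, match="ungrouped"):
            labels = parse_groups(["ACCONLY"])
        assert labels["ACCONLY"] == "ungrouped"

    def test_mapping_table_missing_sequence_errors(self):
        with pytest.raises(ValueError, match="missing"):
            parse_groups(["ACC1 x", "ACC9 y"], rule="mapping_table",
                         mapping_table={"ACC1": "G"})


class TestFindInformativeSites:
    def test_toy_two_group_msa(self):
        msa = toy_msa(
            {"a1 G1 x": "AAC", "a2 G1 x": "AAC", "b1 G2 x": "AAT", "b2 G2 x": "AAT"},
            {"a1 G1 x": "G1", "a2 G1 x": "G1", "b1 G2 x": "G2", "b2 G2 x": "G2"},
        )
        sites = find_informative_sites(msa, "strict")
        got = {(s.ref_position, s.group, s.diagnostic_base) for s in sites}
        assert got == {(2, "G1", "C"), (2, "G2", "T")}
        assert all(s.in_group_fraction == 1.0 for s in sites)

    def test_frequency_boundary_inclusive(self):
        # 9 of 10 in-group A (0.9 >= 0.9), all 8 others C (1.0 >= 0.9)
        rows = {f"g{i} T x": "A" for i in range(9)}
        rows["g9 T x"] = "G"
        rows.update({f"o{i} O x": "C" for i in range(8)})
        groups = {n: ("T" if n.startswith("g") else "O") for n in rows}
        msa = toy_msa({n: r for n, r in rows.items()}, groups)
        sites = find_informative_sites(msa, "frequency", 0.90)
        assert any(s.group == "T" and s.diagnostic_base == "A" for s in sites)
        # the 9-of-10 group is not fixed, so strict mode rejects it
        strict = find_informative_sites(msa, "strict")
        assert not any(s.group == "T" for s in strict)

    def test_gap_leaves_denominator(self):
        # the gapped member drops out, so the remaining 2/2 still fix the site
        msa = toy_msa(
            {"a1 G1 x": "C", "a2 G1 x": "C", "a3 G1 x": "-",
             "b1 G2 x": "T", "b2 G2 x": "T"},
            {"a1 G1 x": "G1", "a2 G1 x": "G1", "a3 G1 x": "G1",
             "b1 G2 x": "G2", "b2 G2 x": "G2"},
        )
        sites = find_informative_sites(msa, "strict")
        assert {(s.group, s.diagnostic_base) for s in sites} == {("G1", "C"), ("G2", "T")}
        assert all(s.in_group_fraction == 1.0 for s in sites)

    def test_reference_gap_columns_skipped(self):
        msa = toy_msa(
            {"r G1 x": "A-C", "a G1 x": "AGC", "b G2 x": "ATT", "c G2 x": "ATT"},
            {"r G1 x": "G1", "a G1 x": "G1", "b G2 x": "G2", "c G2 x": "G2"},
        )
        sites = find_informative_sites(msa, "strict")
        # MSA column 1 is a gap in the reference: only ref positions 0,1 exist
        assert all(s.ref_position in (0, 1) for s in sites)
        assert {(s.ref_position, s.group) for s in sites} == {(1, "G1"), (1, "G2")}

    def test_fewer_than_two_groups_rejected(self):
        msa = toy_msa({"a G x": "ACGT", "b G x": "ACGT"},
                      {"a G x": "G", "b G x": "G"})
        with pytest.raises(ValueError, match="2 groups"):
            find_informative_sites(msa, "strict")

    def test_strict_equals_brute_force_on_random_msas(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_seq = int(rng.integers(4, 12))
            n_col = int(rng.integers(5, 60))
            names, rows, groups = [], [], {}
            for i in range(n_seq):
                name = f"acc{i} G{i % 3} sp"
                names.append(name)
                groups[name] = f"G{i % 3}"
                rows.append(
                    "".join(rng.choice(list("ACGT-N"), p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06])
                            for _ in range(n_col))
                )
            # reference must be gap-poor enough to anchor coordinates
            rows[0] = rows[0].replace("-", "A")
            msa = GroupedMSA(names=names, rows=rows, reference_id=names[0], groups=groups)
            got = {
                (s.ref_position, s.group, s.diagnostic_base)
                for s in find_informative_sites(msa, "strict")
            }
            assert got == brute_force_strict_sites(msa)

    def test_strict_subset_of_frequency(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            names, rows, groups = [], [], {}
            for i in range(8):
                name = f"acc{i} G{i % 2} sp"
                names.append(name)
                groups[name] = f"G{i % 2}"
                rows.append("".join(rng.choice(list("ACGT")) for _ in range(30)))
            msa = GroupedMSA(names=names, rows=rows, reference_id=names[0], groups=groups)
            strict = {
                (s.ref_position, s.group, s.diagnostic_base)
                for s in find_informative_sites(msa, "strict")
            }
            for fraction in (0.75, 0.9, 1.0):
                freq = {
                    (s.ref_position, s.group, s.diagnostic_base)
                    for s in find_informative_sites(msa, "frequency", fraction)
                }
                assert strict <= freq


class TestMaskDamage:
    def test_forward_terminal_t_masked(self):
        aln = make_alignment("f", 0, "ATACGCA")  # T at alignment position 2
        masked = mask_damage(aln, 3)
        assert 1 in masked.masked_read_positions  # query position of that T

    def test_t_outside_window_unmasked(self):
        aln = make_alignment("f", 0, "AAATCGCAA")  # T at position 4 of 9
        masked = mask_damage(aln, 3)
        assert masked.masked_read_positions == frozenset()

    def test_reverse_terminal_a_masked(self):
        aln = make_alignment("r", 0, "CCGCGCA", strand="-")  # ref-forward A at last col
        masked = mask_damage(aln, 3)
        assert 6 in masked.masked_read_positions

    def test_forward_a_not_masked(self):
        aln = make_alignment("f", 0, "AAACGCAAA")
        assert mask_damage(aln, 3).masked_read_positions == frozenset()


SITES_MSA = None


class TestTallySupport:
    def make_sites(self):
        from sedadna.placement import InformativeSite

        return [
            InformativeSite(5, "Cervus", "C", "strict", 1.0, 1.0),
            InformativeSite(8, "Cervus", "G", "strict", 1.0, 1.0),
            InformativeSite(12, "Dama", "T", "strict", 1.0, 1.0),
        ]

    def test_single_matching_observation(self):
        aln = make_alignment("f", 4, "ACAAAAA")  # covers ref 4..10, C at ref 5
        tallies = tally_support([aln], self.make_sites())
        by_group = {t.group: (t.matches, t.overlaps) for t in tallies}
        assert by_group["Cervus"] == (1, 2)  # ref 8 covered too, base A != G
        assert by_group["Dama"] == (0, 0)

    def test_masked_base_invisible(self):
        aln = make_alignment("f", 5, "TAA")  # T at site ref 5, first position
        masked = mask_damage(aln, 3)
        tallies = tally_support([masked], self.make_sites())
        by_group = {t.group: t.overlaps for t in tallies}
        assert by_group["Cervus"] == 0

    def test_hand_enumerated_observations(self):
        # two fragments over three sites; 5 valid overlapping bases, 4 matching
        a = make_alignment("a", 5, "CAAGAAAT")  # sites 5:C, 8:G, 12:T all match
        b = make_alignment("b", 5, "CAAT")  # 5:C match, 8:T mismatch
        tallies = tally_support([a, b], self.make_sites())
        total_matches = sum(t.matches for t in tallies)
        total_overlaps = sum(t.overlaps for t in tallies)
        assert (total_matches, total_overlaps) == (4, 5)

    def test_site_beyond_reference_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            tally_support([], self.make_sites(), reference_length=10)


class TestCallConsensus:
    def cover(self, bases, pos=0):
        return [make_alignment(f"f{i}", pos, b) for i, b in enumerate(bases)]

    def test_two_thirds_majority_called(self):
        calls, seq = call_consensus(self.cover(["A", "A", "C"]), 5)
        assert seq[0] == "A"
        assert calls[0].coverage == 3
        assert calls[0].majority_fraction == Fraction(2, 3)

    def test_even_split_uncalled(self):
        _, seq = call_consensus(self.cover(["A", "C"]), 5)
        assert seq[0] == "N"

    def test_single_coverage_uncalled(self):
        _, seq = call_consensus(self.cover(["A"]), 5)
        assert seq[0] == "N"

    def test_masked_bases_do_not_vote(self):
        # both fragments carry terminal T; masking removes them entirely
        alns = [mask_damage(a, 3) for a in self.cover(["T", "T", "T"])]
        _, seq = call_consensus(alns, 5)
        assert seq[0] == "N"

    def test_called_positions_decrease_with_coverage_threshold(self):
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list("ACGT")) for _ in range(50))
        alns = [
            make_alignment(f"f{i}", int(rng.integers(0, 30)), ref[s:s + 15])
            for i, s in enumerate(rng.integers(0, 30, size=30))
        ]
        # realign sequences to their own coordinates so bases agree with ref
        alns = [
            make_alignment(f"f{i}", s, ref[s:s + 15])
            for i, s in enumerate(int(x) for x in rng.integers(0, 35, size=30))
        ]
        called = []
        for min_cov in (1, 2, 3, 5, 8):
            calls, seq = call_consensus(alns, 50, min_coverage=min_cov)
            called.append(sum(1 for c in seq if c != "N"))
        assert called == sorted(called, reverse=True)

    def test_majority_invariant_per_position(self):
        rng = np.random.default_rng(9)
        ref = "".join(rng.choice(list("ACGT")) for _ in range(40))
        alns = [
            make_alignment(f"f{i}", s, ref[s:s + 12])
            for i, s in enumerate(int(x) for x in rng.integers(0, 28, size=25))
        ]
        calls, _ = call_consensus(alns, 40)
        import math

        for c in calls:
            if c.base != "N":
                assert c.coverage >= 2
                assert c.majority_fraction >= Fraction(2, 3)
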