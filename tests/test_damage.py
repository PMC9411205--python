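"""Substitution profiles, the exact binomial test, authentication, flanks."""

import math

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp
from scipy.stats import binomtest

from sedadna.damage import (
    authenticate,
    binomial_tail,
    filter_mq,
    flank_composition,
    length_stats,
    merge_fragment_sets,
    substitution_profile,
)
from sedadna.fragments import Fragment, revcomp

from conftest import make_alignment


def log_space_tail(k, n, p0):
    """Independent oracle: log-space summation of binomial pmf terms."""
    if k > n:
        return 0.0
    x = np.arange(k, n + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
        + x * np.log(p0) + (n - x) * np.log1p(-p0)
    )
    return float(np.exp(logsumexp(logpmf)))


class TestBinomialTail:
    def test_whole_support_is_one(self):
        assert binomial_tail(0, 10, 0.1) == pytest.approx(1.0)

    def test_all_successes_analytic(self):
        assert binomial_tail(5, 5, 0.1) == pytest.approx(1e-5, rel=1e-9)

    def test_worked_upper_tail(self):
        # sum of pmf at x = 4, 5, 6 for Binomial(6, 0.1)
        assert binomial_tail(4, 6, 0.1) == pytest.approx(0.001270, abs=5e-7)

    @pytest.mark.parametrize("p0", [0.05, 0.1, 0.5])
    def test_matches_log_space_oracle(self, p0):
        for n in range(0, 31):
            for k in range(0, n + 1):
                ours = binomial_tail(k, n, p0)
                theirs = log_space_tail(k, n, p0)
                assert ours == pytest.approx(theirs, rel=1e-12)

    def test_matches_r_style_one_sided_test(self):
        # independent cross-check against scipy's exact binomial test
        for k, n in [(3, 10), (7, 15), (0, 5), (12, 20)]:
            assert binomial_tail(k, n, 0.1) == pytest.approx(
                binomtest(k, n, 0.1, alternative="greater").pvalue, rel=1e-12
            )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 4, 0.1)
        with pytest.raises(ValueError):
            binomial_tail(1, 4, 1.5)


REF = "CATGCCGTACGTACCGTTACGCATGCATCGCCATGCAAGGC"


class TestSubstitutionProfile:
    def test_forward_terminal_ct(self):
        # reference C at the fragment's first position, read T there
        aln = make_alignment("f", 4, "T" + REF[5:15])  # REF[4] == "C"
        prof = substitution_profile([aln], REF, window=5)
        assert prof.frequency(0, 0, "C", "T") == pytest.approx(1.0)
        k5, n5, k3, n3 = prof.terminal_ct()
        assert (k5, n5) == (1, 1)

    def test_reverse_strand_complement_bookkeeping(self):
        # reference-forward G->A at the reference-rightmost column of a
        # reverse-strand alignment is C->T at read 5' position 1
        start = 16  # REF[16:21] == "TACGC"; rightmost ref base G at 20
        sam_seq = REF[16:20] + "A"  # G read as A
        aln = make_alignment("r", start, sam_seq, strand="-")
        prof = substitution_profile([aln], REF, window=5)
        assert prof.frequency(0, 0, "C", "T") == pytest.approx(1.0)

    def test_two_strand_hand_oracle(self):
        # forward C->T at 5' pos 1 plus reverse G->A at its 5' terminus:
        # both count in the same C->T numerator; a fragment starting on A
        # joins no C denominator at position 1
        fwd = make_alignment("f", 4, "T" + REF[5:15])
        rev = make_alignment("r", 16, REF[16:20] + "A", strand="-")
        neutral = make_alignment("n", 8, REF[8:18])  # REF[8] == "A": no C at pos 1
        prof = substitution_profile([fwd, rev, neutral], REF, window=3)
        k5, n5, _, _ = prof.terminal_ct()
        assert (k5, n5) == (2, 2)
        # the A-start fragment is in the A denominator instead
        assert prof.denom[0, 0, "ACGT".index("A")] == 1

    def test_denominator_bounded_by_fragment_length(self):
        alns = [make_alignment("a", 0, REF[0:6]), make_alignment("b", 0, REF[0:20])]
        prof = substitution_profile(alns, REF, window=10)
        for i in range(10):
            n_long_enough = sum(1 for a in alns if a.read_length >= i + 1)
            assert prof.denom[0, i].sum() <= n_long_enough

    def test_wrong_reference_id_raises(self):
        aln = make_alignment("f", 0, REF[0:10], reference_id="other")
        with pytest.raises(ValueError, match="other"):
            substitution_profile([aln], REF, 5, reference_id="ref")


class TestAuthenticate:
    def make_profile(self, k5, n5, k3, n3):
        import numpy as np

        from sedadna.damage import DamageProfile

        denom = np.zeros((2, 5, 4), dtype=np.int64)
        numer = np.zeros((2, 5, 4, 4), dtype=np.int64)
        c, t = 1, 3
        denom[0, 0, c], numer[0, 0, c, t] = n5, k5
        denom[1, 0, c], numer[1, 0, c, t] = n3, k3
        return DamageProfile(5, denom, numer)

    def test_both_ends_significant_is_ancient(self):
        res = authenticate(self.make_profile(5, 5, 4, 6))
        assert res.p5 == pytest.approx(1e-5, rel=1e-9)
        assert res.p3 == pytest.approx(0.001270, abs=5e-7)
        assert res.ancient == "yes"

    def test_weak_five_prime_not_ancient(self):
        res = authenticate(self.make_profile(1, 10, 6, 6))
        assert res.p5 == pytest.approx(log_space_tail(1, 10, 0.1), rel=1e-9)
        assert res.p5 > 0.05
        assert res.ancient == "no"

    def test_empty_denominator_not_assessable(self):
        assert authenticate(self.make_profile(0, 0, 4, 6)).ancient == "not_assessable"

    def test_monotone_in_k5(self):
        verdicts = [
            authenticate(self.make_profile(k5, 20, 10, 20)).ancient for k5 in range(21)
        ]
        # once ancient, adding more damage never flips the call back
        first_yes = verdicts.index("yes")
        assert all(v == "yes" for v in verdicts[first_yes:])


class TestFilterMqAndMerge:
    def test_mq_threshold_inclusive(self):
        alns = [make_alignment(f"f{q}", 0, REF[0:10], mapping_quality=q)
                for q in (24, 25, 37)]
        assert [a.mapping_quality for a in filter_mq(alns, 25)] == [25, 37]
        assert filter_mq([], 25) == []
        assert filter_mq(alns, 0) == alns

    def test_merge_conserves_and_checks_reference(self):
        sets = [
            [make_alignment(f"s{i}_{j}", 0, REF[0:10], library_id=f"L{i}")
             for j in range(n)]
            for i, n in enumerate([15, 5, 9, 12, 21, 8])
        ]
        merged = merge_fragment_sets(sets)
        assert len(merged) == 70
        assert {a.library_id for a in merged} == {f"L{i}" for i in range(6)}
        assert merge_fragment_sets([sets[0]]) == sets[0]
        assert merge_fragment_sets([[], sets[1]]) == sets[1]
        bad = [make_alignment("x", 0, REF[0:10], reference_id="other")]
        with pytest.raises(ValueError, match="mixed references"):
            merge_fragment_sets([sets[0], bad])


class TestFlankComposition:
    def test_forward_upstream_decamer(self):
        aln = make_alignment("f", 10, REF[10:20])
        comp = flank_composition([aln], REF, flank_window=10)
        # offsets -10..-1 upstream of the 5' end are exactly REF[0:10]
        for row, off in enumerate(range(-10, 0)):
            base = REF[10 + off]
            assert comp.counts5[row, "ACGT".index(base)] == 1
            assert comp.counts5[row].sum() == 1

    def test_reference_start_excludes_upstream(self):
        aln = make_alignment("f", 0, REF[0:10])
        comp = flank_composition([aln], REF, flank_window=5)
        assert comp.counts5[:5].sum() == 0  # nothing upstream of position 0

    def test_reverse_strand_is_complemented(self):
        aln = make_alignment("r", 10, REF[10:20], strand="-")
        comp = flank_composition([aln], REF, flank_window=1)
        # 5' flank of a reverse read = complement of the base after the interval
        flank = revcomp(REF[20])
        assert comp.counts5[0, "ACGT".index(flank)] == 1

    def test_frequencies_sum_to_one(self):
        alns = [make_alignment(f"f{i}", 5 + i, REF[5 + i : 20 + i]) for i in range(5)]
        comp = flank_composition(alns, REF, flank_window=3)
        df = comp.frequencies("5p")
        sums = df[list("ACGT")].sum(axis=1).dropna()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestLengthStats:
    def test_mean_and_max(self):
        frs = [Fragment(id="a", sequence="A" * 40), Fragment(id="b", sequence="C" * 44)]
        st = length_stats(frs)
        assert st.mean == pytest.approx(42.0)
        assert st.max == 44
        assert st.histogram == {40: 1, 44: 1}

    def test_single_fragment(self):
        st = length_stats([Fragment(id="a", sequence="G" * 51)])
        assert (st.mean, st.max) == (51.0, 51)

    def test_histogram_conserves_count(self):
        frs = [Fragment(id=f"f{i}", sequence="A" * (35 + i % 4)) for i in range(20)]
        st = length_stats(frs)
        assert sum(st.histogram.values()) == 20

    def test_empty_input_flagged(self):
        with pytest.warns(UserWarning, match="empty"):
            st = length_stats([])
        assert st.mean is None and st.histogram == {}
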