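"""Counting module: worked instances, brute-force oracle, mode properties."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from dyadscan import (GappedFactorQuery, Mode, SequenceSet, annotate_hh,
                      annotate_relaxed, annotate_tandem, annotate_th_exact,
                      build_index, count, count_ht, naive_count, query_th)
from dyadscan.counts import th_exact_query

from conftest import random_query_words, random_sequence_set

ALL_MODES = list(Mode)


class TestInterleavingInstance:
    """x = GATATAGAT, y = G at {1,7}, z = T at {3,5,9}, d = 8."""

    @pytest.mark.parametrize("annotate, expected", [
        (annotate_hh, 4),          # pairs (1,3),(1,5),(1,9),(7,9)
        (annotate_relaxed, 3),     # two pairs for the first y, one for the second
        (annotate_tandem, 2),      # closest-pair only: (1,3),(7,9)
    ])
    def test_indexes(self, interleave_index, annotate, expected):
        y = interleave_index.locus("G")
        z = interleave_index.locus("T")
        assert annotate(interleave_index, y, 8)[z] == expected

    def test_naive_oracle_agrees(self):
        assert naive_count("GATATAGAT", "G", "T", 8, Mode.HH) == 4
        assert naive_count("GATATAGAT", "G", "T", 8, Mode.RELAXED_TANDEM) == 3
        assert naive_count("GATATAGAT", "G", "T", 8, Mode.TANDEM) == 2


class TestCountDispatch:
    def test_hh_window_too_small(self, agct_index):
        assert count(agct_index, GappedFactorQuery("AG", "AG", 1, Mode.HH)) == 0

    def test_hh_example(self, agct_index):
        assert count(agct_index, GappedFactorQuery("AG", "CT", 3, Mode.HH)) == 2

    def test_th_gap_zero_adjacency(self, agct_index):
        assert count(agct_index, GappedFactorQuery("AG", "CT", 0, Mode.TH)) == 2

    def test_ht_example(self, agct_index):
        assert count(agct_index, GappedFactorQuery("AG", "CT", 4, Mode.HT)) == 2

    def test_absent_component_is_zero(self, agct_index):
        for mode in ALL_MODES:
            q = GappedFactorQuery("AG", "TT", 3, mode)
            assert count(agct_index, q) == 0

    def test_hh_rejects_distance_zero(self, agct_index):
        with pytest.raises(ValueError):
            annotate_hh(agct_index, agct_index.locus("AG"), 0)

    def test_invalid_query_construction(self):
        with pytest.raises(ValueError):
            GappedFactorQuery("", "A", 3)
        with pytest.raises(ValueError):
            GappedFactorQuery("A", "A", -1)


class TestTailToHead:
    def test_exact_table_beyond_record_is_zero(self, agct_index):
        y = agct_index.locus("AG")
        table = annotate_th_exact(agct_index, y, 50)
        assert all(c == 0 for c in table.counts)

    def test_telescoping_sum_equals_unbounded(self):
        rng = random.Random(21)
        for _ in range(20):
            seqs = random_sequence_set(rng, max_n=60)
            idx = build_index(seqs)
            y, z = random_query_words(rng, seqs)
            n = max(seqs.lengths)
            got = query_th(idx, y, z, n)
            exp = naive_count(seqs, y, z, n, Mode.TH)
            assert got == exp

    def test_case_boundary_routes_agree(self, agct_index):
        """|y'| + h == |maximal y|: overlap concatenation equals the
        exact-distance table read at adjusted gap 0."""
        y_prime = "AG"  # maximal word AGCTA, |y'| + 3 == 5
        alpha = agct_index.locus(y_prime)
        z = "GCT"
        case2 = th_exact_query(agct_index, y_prime, z, 3)
        case1_table = annotate_th_exact(agct_index, alpha, 0)
        assert case2 == case1_table[agct_index.locus(z)]
        assert case2 == naive_count("AGCTAGCTAAA", y_prime, z, 3,
                                    Mode.TH, d_min=3)

    def test_monotone_in_d(self, agct_index):
        vals = [query_th(agct_index, "AG", "A", d) for d in range(8)]
        assert vals == sorted(vals)

    def test_gap_range_lower_bound(self, agct_index):
        full = query_th(agct_index, "AG", "A", 6)
        head = query_th(agct_index, "AG", "A", 2)
        tail = query_th(agct_index, "AG", "A", 6, d_min=3)
        assert head + tail == full


class TestHeadToTail:
    def test_component_longer_than_window(self, agct_index):
        assert count(agct_index, GappedFactorQuery("AG", "CTA", 2,
                                                   Mode.HT)) == 0

    def test_exclude_within_y(self):
        # y = AGCT: its own substrings start inside the y occurrence
        idx = build_index("AGCTAGCTAAA")
        y = idx.locus("AGCT")
        with_self = count_ht(idx, y, 4)
        without = count_ht(idx, y, 4, exclude_within_y=True)
        assert with_self.count_word("GC") == 2   # inside both y copies
        assert without.count_word("GC") == 0

    def test_window_table_matches_naive(self):
        rng = random.Random(22)
        for _ in range(30):
            seqs = random_sequence_set(rng, max_n=60)
            idx = build_index(seqs)
            y, z = random_query_words(rng, seqs)
            d = rng.randint(1, 12)
            got = count(idx, GappedFactorQuery(y, z, d, Mode.HT))
            assert got == naive_count(seqs, y, z, d, Mode.HT)


class TestOracleEquivalence:
    def test_all_modes_small_random(self):
        rng = random.Random(23)
        for trial in range(60):
            sigma = "ACGT" if trial % 2 else "AC"
            seqs = random_sequence_set(rng, max_n=100, sigma=sigma)
            idx = build_index(seqs)
            for _ in range(3):
                y, z = random_query_words(rng, seqs)
                d = rng.randint(1, 15)
                for mode in ALL_MODES:
                    got = count(idx, GappedFactorQuery(y, z, d, mode))
                    exp = naive_count(seqs, y, z, d, mode)
                    assert got == exp, (seqs.records, y, z, d, mode)

    def test_class_consistency_hh_ht(self):
        """Counts are invariant under replacing either component by any
        word sharing its locus."""
        idx = build_index("AGCTAGCTAAA")
        for mode in (Mode.HH, Mode.HT):
            base = count(idx, GappedFactorQuery("AG", "CT", 5, mode))
            for y in ("AG", "AGC", "AGCT", "AGCTA"):
                for z in ("CT", "CTA"):
                    assert count(idx, GappedFactorQuery(y, z, 5, mode)) == base

    def test_ordering_tandem_relaxed_hh(self):
        rng = random.Random(24)
        for _ in range(15):
            seqs = random_sequence_set(rng, max_n=80)
            idx = build_index(seqs)
            y_nodes = [n for n in idx.nodes if n.has_word_class][:10]
            d = rng.randint(1, 10)
            for y in y_nodes:
                hh = annotate_hh(idx, y, d).counts
                rel = annotate_relaxed(idx, y, d).counts
                tan = annotate_tandem(idx, y, d).counts
                for a, b, c in zip(tan, rel, hh):
                    assert a <= b <= c

    def test_counts_bounded_by_occurrences_times_d(self):
        rng = random.Random(25)
        seqs = random_sequence_set(rng, max_n=80)
        idx = build_index(seqs)
        d = 6
        for y in (n for n in idx.nodes if n.has_word_class):
            table = annotate_hh(idx, y, d)
            bound = y.occurrence_count * d
            assert all(0 <= c <= bound for c in table.counts)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.text(alphabet="AC", min_size=4, max_size=50),
       st.integers(min_value=1, max_value=10),
       st.data())
def test_tree_counts_equal_naive_property(x, d, data):
    """Property: tree-annotated counts equal the literal definitions for
    every mode, on arbitrary binary strings."""
    i = data.draw(st.integers(0, len(x) - 1))
    j = data.draw(st.integers(0, len(x) - 1))
    y = x[i: i + data.draw(st.integers(1, 3))]
    z = x[j: j + data.draw(st.integers(1, 3))]
    seqs = SequenceSet.from_strings(x, alphabet="AC")
    idx = build_index(seqs)
    for mode in ALL_MODES:
        assert count(idx, GappedFactorQuery(y, z, d, mode)) == \
            naive_count(seqs, y, z, d, mode)
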