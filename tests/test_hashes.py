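"""The nucleotide-projection hash family: enumeration, evaluation, rolling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kmercomp.hashes import (
    AmbiguousBaseError,
    HashFunctionSpec,
    enumerate_functions,
    enumerate_labelings_bruteforce,
    get_function,
    hash_kmer,
    parse_functions,
    reverse_complement,
    rolling_hashes,
    sequence_codes,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestEnumeration:
    def test_family_has_seven_members_three_balanced(self):
        fns = enumerate_functions()
        assert len(fns) == 7
        assert sum(f.balanced for f in fns) == 3
        assert [f.id for f in fns] == [1, 2, 3, 4, 5, 6, 7]

    def test_matches_bruteforce_equivalence_classes(self):
        """All 16 labelings, minus constants, merged under complement, give
        the same seven zero-sets."""
        brute = enumerate_labelings_bruteforce()
        assert len(brute) == 7
        assert [set(s) for s in brute] == [set(f.zero_set) for f in enumerate_functions()]

    def test_canonical_zero_sets(self):
        by_id = {f.id: f.zero_set for f in enumerate_functions()}
        assert by_id[1] == frozenset("AC")
        assert by_id[2] == frozenset("AG")
        assert by_id[3] == frozenset("AT")
        assert by_id[4] == frozenset("A")
        assert by_id[7] == frozenset("T")

    def test_balanced_specs_have_two_letters_including_A(self):
        for f in enumerate_functions():
            if f.balanced:
                assert len(f.zero_set) == 2 and "A" in f.zero_set

    def test_degenerate_zero_sets_rejected(self):
        with pytest.raises(ValueError):
            HashFunctionSpec(8, frozenset())
        with pytest.raises(ValueError):
            HashFunctionSpec(8, frozenset("ACGT"))

    def test_parse_functions_aliases_and_duplicates(self):
        combo = parse_functions("b1,b2,b3,u1")
        assert [f.id for f in combo] == [1, 2, 3, 4]
        with pytest.raises(ValueError):
            parse_functions("f1,b1")
        with pytest.raises(KeyError):
            get_function("f9")


class TestHashKmer:
    @pytest.mark.parametrize(
        "fname, kmer, expected",
        [
            ("f1", "ACGT", 0b0011),
            ("f4", "ACGT", 0b0111),
            ("f2", "AAAA", 0),
            ("f1", "acgt", 0b0011),  # case-insensitive
        ],
    )
    def test_known_codes(self, fname, kmer, expected):
        assert hash_kmer(get_function(fname), kmer) == expected

    def test_leftmost_base_is_most_significant(self):
        f1 = get_function("f1")
        assert hash_kmer(f1, "GA") == 0b10
        assert hash_kmer(f1, "AG") == 0b01

    def test_ambiguous_base_rejected(self):
        with pytest.raises(AmbiguousBaseError):
            hash_kmer(get_function("f1"), "ACNT")

    def test_per_position_bit_balance(self):
        """Balanced functions map the 4 letters 2-to-0/2-to-1, unbalanced
        1-to-0/3-to-1, at every position."""
        for f in enumerate_functions():
            bits = [hash_kmer(f, nt) for nt in "ACGT"]
            zeros = bits.count(0)
            assert zeros == (2 if f.balanced else 1)


class TestRolling:
    def test_worked_example(self):
        f1 = get_function("f1")
        assert list(rolling_hashes(f1, "ACGTA", 4)) == [(0, 0b0011), (1, 0b0110)]

    def test_short_sequence_yields_nothing(self, functions):
        for f in functions:
            assert list(rolling_hashes(f, "ACG", 4)) == []

    def test_ambiguous_bases_skip_and_restart(self):
        f1 = get_function("f1")
        out = dict(rolling_hashes(f1, "ACNGT", 2))
        assert sorted(out) == [0, 3]
        assert out[0] == hash_kmer(f1, "AC")
        assert out[3] == hash_kmer(f1, "GT")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=0, max_size=120),
        k=st.sampled_from([3, 15, 33]),
        fid=st.integers(1, 7),
    )
    def test_rolling_equals_direct_recomputation(self, seq, k, fid):
        """The O(1) rolling update reproduces an independent per-position
        hash at every k-mer, skipping windows with ambiguous bases."""
        f = get_function(f"f{fid}")
        expected = []
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) <= set("ACGT"):
                expected.append((i, hash_kmer(f, window)))
        assert list(rolling_hashes(f, seq, k)) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGTN", min_size=0, max_size=120), k=st.sampled_from([3, 7, 15]))
    def test_vectorised_codes_match_rolling(self, seq, k):
        fns = enumerate_functions()[:4]
        pos, codes = sequence_codes(fns, seq, k)
        for fi, f in enumerate(fns):
            expected = dict(rolling_hashes(f, seq, k))
            assert list(pos) == sorted(expected)
            assert [int(c) for c in codes[fi]] == [expected[p] for p in pos]


class TestInjectivity:
    @staticmethod
    def _all_codes(f, k):
        fns = [f]
        kmers = ["".join("ACGT"[(i >> (2 * j)) & 3] for j in range(k)) for i in range(4**k)]
        return np.array([hash_kmer(f, s) for s in kmers])

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_balanced_pairs_are_jointly_injective(self, k, balanced):
        """No two distinct k-mers agree simultaneously on any two balanced
        functions (exhaustive over all 4^k k-mers)."""
        codes = {f.id: self._all_codes(f, k) for f in balanced}
        for i, fa in enumerate(balanced):
            for fb in balanced[i + 1 :]:
                pairs = codes[fa.id] * (1 << k) + codes[fb.id]
                assert len(np.unique(pairs)) == 4**k

    @pytest.mark.parametrize("k", [2, 4])
    def test_pairs_with_unbalanced_collide(self, k, balanced, unbalanced):
        """Any pair involving an unbalanced function must have a
        counterexample: two distinct k-mers with identical code pairs."""
        f_b, f_u = balanced[0], unbalanced[0]
        cb, cu = self._all_codes(f_b, k), self._all_codes(f_u, k)
        pairs = cb * (1 << k) + cu
        assert len(np.unique(pairs)) < 4**k


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq, expected", [("ACGT", "ACGT"), ("AACG", "CGTT"), ("N", "N"), ("", "")]
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGTN", max_size=100))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")
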