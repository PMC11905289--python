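"""Alphabet-ordering construction: initializations, restriction, inversion."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlbwt_order import (
    AlphabetOrdering,
    chapin_tate_ordering,
    derive_alphabet,
    fda_ordering,
    init_ordering,
    inverse_permutation,
    ipct_ordering,
    random_ordering,
    restrict,
    reverse,
    vowels_ordering,
)


def as_str(ordering: AlphabetOrdering) -> str:
    return ordering.as_string()


class TestDeriveAlphabet:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("cacatcg", "acgt"),
            ("aaaa", "a"),
            ("acacacbbacbac", "abc"),
        ],
    )
    def test_distinct_symbols_in_byte_order(self, text, expected):
        assert bytes(derive_alphabet(text)).decode() == expected

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            derive_alphabet("")


class TestInitOrdering:
    @pytest.mark.parametrize(
        "method, expected",
        [
            ("ascii", "acgt"),
            ("first_appearance", "catg"),
            # counts: c=3, a=2, g=1, t=1; g/t tie broken by byte order
            ("most_frequent", "cagt"),
            ("least_frequent", "gtac"),
        ],
    )
    def test_deterministic_methods_on_cacatcg(self, method, expected):
        assert as_str(init_ordering("cacatcg", method)) == expected

    @pytest.mark.parametrize(
        "method",
        ["ascii", "first_appearance", "least_frequent", "most_frequent",
         "chapin_tate", "ipct", "vowels"],
    )
    def test_every_method_is_a_permutation_of_the_alphabet(self, method):
        text = "the quick brown fox, 1234!"
        ordering = init_ordering(text, method)
        assert sorted(ordering.symbols) == sorted(derive_alphabet(text))

    def test_non_random_methods_bit_identical_across_calls(self):
        text = "abracadabra"
        for method in ("ascii", "first_appearance", "most_frequent"):
            assert init_ordering(text, method) == init_ordering(text, method)

    def test_random_requires_seed(self):
        with pytest.raises(ValueError):
            init_ordering("abc", "random")

    def test_random_reproducible_from_seed(self):
        a = init_ordering("the quick brown fox", "random", seed=11)
        b = init_ordering("the quick brown fox", "random", seed=11)
        c = init_ordering("the quick brown fox", "random", seed=12)
        assert a.symbols == b.symbols
        assert sorted(c.symbols) == sorted(a.symbols)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            init_ordering("abc", "simulated_annealing")


class TestChapinTate:
    def test_is_a_256_byte_permutation(self):
        ct = chapin_tate_ordering()
        assert sorted(ct.symbols) == list(range(256))

    def test_vowels_lead_each_letter_block(self):
        ct = as_str(chapin_tate_ordering())
        uppers = [c for c in ct if "A" <= c <= "Z"]
        lowers = [c for c in ct if "a" <= c <= "z"]
        assert "".join(uppers) == "AEIOUBCDGFHRLSMNPQJKTWVXYZ"
        assert "".join(lowers) == "aeioubcdgfhrlsmnpqjktwvxyz"

    def test_bang_at_swap_and_punctuation_rearrangement(self):
        ct = chapin_tate_ordering()
        assert ct.symbols[ord("!")] == ord("@")
        assert ct.symbols[ord("@")] == ord("!")
        assert bytes(ct.symbols[ord("+"):ord(".") + 1]) == b"+-,."

    def test_unmentioned_bytes_keep_natural_positions(self):
        ct = chapin_tate_ordering()
        for b in list(range(33)) + list(range(48, 58)) + list(range(123, 256)):
            assert ct.symbols[b] == b


class TestIPCT:
    def test_letter_block_order(self):
        ip = as_str(ipct_ordering())
        uppers = "".join(c for c in ip if "A" <= c <= "Z")
        assert uppers == "AFGHBJIKCSTMOPDQRLNUEWVXYZ"

    def test_vowel_relative_order_is_a_i_o_u_e(self):
        uppers = [c for c in as_str(ipct_ordering()) if "A" <= c <= "Z"]
        vowel_seq = [c for c in uppers if c in "AEIOU"]
        assert vowel_seq == list("AIOUE")

    def test_is_inverse_of_chapin_tate_on_letters(self):
        ct_letters = AlphabetOrdering(
            tuple(s for s in chapin_tate_ordering().symbols if 65 <= s <= 90)
        )
        ip_letters = tuple(
            s for s in ipct_ordering().symbols if 65 <= s <= 90
        )
        assert inverse_permutation(ct_letters).symbols == ip_letters

    def test_shares_punctuation_changes_with_chapin_tate(self):
        ip = ipct_ordering()
        assert ip.symbols[ord("!")] == ord("@")
        assert bytes(ip.symbols[ord("+"):ord(".") + 1]) == b"+-,."


class TestPermutationOps:
    def test_inverse_of_identity_is_identity(self):
        ident = AlphabetOrdering.from_string("abcz")
        assert inverse_permutation(ident).symbols == ident.symbols

    def test_inverse_of_bca_brute_force(self):
        # brute-force over all 6 permutations of sigma=3 confirms (b,c,a)->(c,a,b)
        assert inverse_permutation(
            AlphabetOrdering.from_string("bca")
        ).as_string() == "cab"

    @settings(deadline=None, max_examples=50)
    @given(st.permutations(list(range(8))))
    def test_inverse_is_an_involution(self, perm):
        p = AlphabetOrdering(tuple(perm))
        assert inverse_permutation(inverse_permutation(p)).symbols == p.symbols

    def test_reverse_flips_order(self):
        assert as_str(reverse(AlphabetOrdering.from_string("abc"))) == "cba"

    def test_restrict_preserves_relative_order(self):
        full = AlphabetOrdering(tuple(range(256)), "ascii")
        assert as_str(restrict(full, b"tagc")) == "acgt"

    def test_restrict_chapin_tate_vowels_precede_consonants(self):
        sub = restrict(chapin_tate_ordering(), b"ABE")
        assert as_str(sub) == "AEB"

    def test_restrict_full_domain_is_identity(self):
        p = AlphabetOrdering.from_string("gcta")
        assert restrict(p, b"acgt").symbols == p.symbols

    def test_restrict_nesting_idempotence(self):
        p = chapin_tate_ordering()
        big, small = b"AEIBCDxyz", b"ABE"
        assert restrict(restrict(p, big), small) == restrict(p, small)

    def test_restrict_missing_symbol_rejected(self):
        with pytest.raises(ValueError):
            restrict(AlphabetOrdering.from_string("abc"), b"abd")


class TestVowelsAndRandom:
    def test_vowels_first_then_natural(self):
        assert as_str(vowels_ordering(b"beaz")) == "aebz"

    def test_vowels_listed_order_both_cases(self):
        v = as_str(vowels_ordering(b"AEIOUaeiouzb"))
        assert v.startswith("aeiouAEIOU")

    def test_random_ordering_equal_seeds_identical(self):
        assert random_ordering(b"abcdefgh", 5) == random_ordering(b"abcdefgh", 5)

    def test_random_ordering_is_permutation(self):
        r = random_ordering(b"abcdefgh", 99)
        assert sorted(r.symbols) == sorted(b"abcdefgh")


class TestFdaPlugin:
    def test_partial_order_completed_by_toposort(self):
        # externally supplied partial order: t before a, g before c
        ordering = fda_ordering(b"acgt", [(ord("t"), ord("a")),
                                          (ord("g"), ord("c"))])
        s = ordering.as_string()
        assert s.index("t") < s.index("a")
        assert s.index("g") < s.index("c")
        assert sorted(ordering.symbols) == sorted(b"acgt")

    def test_deterministic_tie_break(self):
        a = fda_ordering(b"acgt", [(ord("t"), ord("a"))])
        b = fda_ordering(b"acgt", [(ord("t"), ord("a"))])
        assert a == b

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            fda_ordering(b"ab", [(97, 98), (98, 97)])


def test_duplicate_symbols_rejected():
    with pytest.raises(ValueError):
        AlphabetOrdering((97, 97, 98))
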