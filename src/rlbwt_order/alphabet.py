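"""Alphabet orderings for the Burrows-Wheeler transform.

The comparison order used to sort rotations (or suffixes) is a free
parameter of the BWT: any permutation of the text's distinct symbols is a
valid alphabet ordering, and the choice changes how strongly the transform
clusters equal symbols.  This module represents orderings, derives them
from texts, and constructs the standard family of initialization orderings
used to seed local search: ASCII, first appearance, least/most frequent,
the hand-tuned Chapin-Tate ordering and its inverse permutation, a
vowels-first ordering, seeded random shuffles, and a plugin hook for
orderings produced externally from a partial order.

Symbols are byte values (ints in 0..255).  The end-marker sentinel is never
a member of an ordering; it is implicitly strictly least everywhere.
"""

from __future__ import annotations

import heapq
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "AlphabetOrdering",
    "as_bytes",
    "derive_alphabet",
    "init_ordering",
    "INIT_METHODS",
    "ascii_ordering",
    "first_appearance_ordering",
    "least_frequent_ordering",
    "most_frequent_ordering",
    "chapin_tate_ordering",
    "ipct_ordering",
    "vowels_ordering",
    "random_ordering",
    "fda_ordering",
    "inverse_permutation",
    "restrict",
    "reverse",
    "fisher_yates",
]

#: Vowels in the order they are placed at the front of a vowels-first ordering.
VOWELS = b"aeiouAEIOU"

# Chapin-Tate consonant/vowel ordering of the letter block: vowels lead,
# consonants follow in the hand-tuned order B C D G F H R L S M N P Q J K T W V X Y Z.
_CT_LETTERS = "AEIOUBCDGFHRLSMNPQJKTWVXYZ"
_NATURAL_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
# The inverse permutation of the letter block: letter k of the natural
# alphabet moves to the rank it holds in the Chapin-Tate order, spacing the
# vowels out as A < I < O < U < E.
_IPCT_LETTERS = "".join(
    _NATURAL_LETTERS[_CT_LETTERS.index(c)] for c in _NATURAL_LETTERS
)


def as_bytes(text: str | bytes | bytearray) -> bytes:
    """Coerce a text to raw bytes (str via latin-1, one symbol per byte)."""
    if isinstance(text, str):
        return text.encode("latin-1")
    return bytes(text)


@dataclass(frozen=True)
class AlphabetOrdering:
    """A permutation of an alphabet, smallest symbol first.

    The sentinel is implicitly least and never appears in ``symbols``.

    Parameters
    ----------
    symbols
        Distinct byte values in comparison order (rank 0 = smallest).
    source_label
        Free-text provenance tag, e.g. ``"ascii"`` or ``"random[7]"``.
    """

    symbols: tuple[int, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        syms = tuple(int(s) for s in self.symbols)
        if len(set(syms)) != len(syms):
            raise ValueError("ordering contains repeated symbols")
        for s in syms:
            if not 0 <= s <= 255:
                raise ValueError(f"symbol {s} outside byte range")
        object.__setattr__(self, "symbols", syms)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[int]:
        return iter(self.symbols)

    def rank(self, symbol: int) -> int:
        """Rank of ``symbol`` in this ordering (0 = smallest)."""
        return self._rank_map()[symbol]

    def _rank_map(self) -> dict[int, int]:
        return {s: k for k, s in enumerate(self.symbols)}

    def covers(self, alphabet: Iterable[int]) -> bool:
        return set(alphabet) <= set(self.symbols)

    def as_string(self) -> str:
        """Render the ordering as a latin-1 string, smallest first."""
        return bytes(self.symbols).decode("latin-1")

    @classmethod
    def from_string(cls, s: str, label: str = "") -> "AlphabetOrdering":
        return cls(tuple(as_bytes(s)), label)


def derive_alphabet(text: str | bytes) -> tuple[int, ...]:
    """Distinct symbols of ``text`` sorted by natural byte value.

    Raises ``ValueError`` on empty text: there is nothing to order.
    """
    data = as_bytes(text)
    if not data:
        raise ValueError("empty text has no alphabet to order")
    return tuple(sorted(set(data)))


# ---------------------------------------------------------------------------
# Permutation primitives
# ---------------------------------------------------------------------------

def fisher_yates(items: Sequence[int], rng: random.Random) -> list[int]:
    """Fisher-Yates shuffle, explicit so the draw sequence is pinned down.

    Swaps position i with a uniform position in [i, len) for i = 0..len-2,
    consuming exactly len-1 draws from ``rng``.
    """
    out = list(items)
    n = len(out)
    for i in range(n - 1):
        j = rng.randrange(i, n)
        out[i], out[j] = out[j], out[i]
    return out


def reverse(ordering: AlphabetOrdering) -> AlphabetOrdering:
    """Flip the comparison order of every symbol."""
    return AlphabetOrdering(
        tuple(reversed(ordering.symbols)),
        f"reverse({ordering.source_label})",
    )


def inverse_permutation(ordering: AlphabetOrdering) -> AlphabetOrdering:
    """Standard permutation inverse on ranks.

    If the ordering places the symbol of natural rank ``p[k]`` at rank ``k``,
    the inverse places the symbol of natural rank ``k`` at rank ``p[k]``.
    Inversion is an involution: ``inverse(inverse(x)) == x``.
    """
    natural = sorted(ordering.symbols)
    index = {s: i for i, s in enumerate(natural)}
    perm = [index[s] for s in ordering.symbols]
    inv = [0] * len(perm)
    for k, p in enumerate(perm):
        inv[p] = k
    return AlphabetOrdering(
        tuple(natural[q] for q in inv),
        f"inverse({ordering.source_label})",
    )


def restrict(
    ordering: AlphabetOrdering, alphabet: Iterable[int]
) -> AlphabetOrdering:
    """Subsequence of ``ordering`` over ``alphabet``, relative order kept.

    Full-byte orderings (Chapin-Tate, its inverse, vowels) are defined over
    all 256 bytes and restricted to a concrete text's alphabet this way.
    """
    wanted = set(alphabet)
    missing = wanted - set(ordering.symbols)
    if missing:
        raise ValueError(
            f"alphabet symbols {sorted(missing)} absent from ordering"
        )
    return AlphabetOrdering(
        tuple(s for s in ordering.symbols if s in wanted),
        ordering.source_label,
    )


# ---------------------------------------------------------------------------
# Initialization orderings
# ---------------------------------------------------------------------------

def ascii_ordering(text: str | bytes) -> AlphabetOrdering:
    """Natural (extended-ASCII) byte order of the text's alphabet."""
    return AlphabetOrdering(derive_alphabet(text), "ascii")


def first_appearance_ordering(text: str | bytes) -> AlphabetOrdering:
    """Symbols ordered by their first appearance in the text."""
    data = as_bytes(text)
    if not data:
        raise ValueError("empty text")
    seen: dict[int, None] = {}
    for b in data:
        seen.setdefault(b, None)
    return AlphabetOrdering(tuple(seen), "first_appearance")


def _frequency_ordering(text: str | bytes, most_first: bool) -> AlphabetOrdering:
    data = as_bytes(text)
    if not data:
        raise ValueError("empty text")
    counts = Counter(data)
    sign = -1 if most_first else 1
    # Ties broken by natural byte order (deterministic).
    syms = sorted(counts, key=lambda s: (sign * counts[s], s))
    label = "most_frequent" if most_first else "least_frequent"
    return AlphabetOrdering(tuple(syms), label)


def least_frequent_ordering(text: str | bytes) -> AlphabetOrdering:
    """Symbols ordered by occurrence count, least frequent first."""
    return _frequency_ordering(text, most_first=False)


def most_frequent_ordering(text: str | bytes) -> AlphabetOrdering:
    """Symbols ordered by occurrence count, most frequent first."""
    return _frequency_ordering(text, most_first=True)


def _letter_block_table(letters: str) -> list[int]:
    """Full 256-byte table: natural order, '!'<->'@' swapped, '+,-.' to
    '+-,.', and both case blocks rearranged to ``letters``."""
    table = list(range(256))
    table[ord("!")], table[ord("@")] = ord("@"), ord("!")
    table[ord("+"):ord(".") + 1] = [ord(c) for c in "+-,."]
    table[ord("A"):ord("Z") + 1] = [ord(c) for c in letters]
    table[ord("a"):ord("z") + 1] = [ord(c.lower()) for c in letters]
    return table


def chapin_tate_ordering() -> AlphabetOrdering:
    """The hand-tuned Chapin-Tate ordering over the full byte range.

    Natural byte order modified by: '@' replaces '!' (and vice versa),
    '+,-.' rearranged to '+-,.', vowels AEIOU / aeiou brought to the front
    of the upper-/lower-case letter block, and the consonants of each block
    reordered B<C<D<G<F<H<R<L<S<M<N<P<Q<J<K<T<W<V<X<Y<Z.  All other bytes
    keep their natural relative positions.
    """
    return AlphabetOrdering(tuple(_letter_block_table(_CT_LETTERS)), "chapin_tate")


def ipct_ordering() -> AlphabetOrdering:
    """Inverse permutation of the Chapin-Tate letter block.

    Spaces the vowels out (A < I < O < U < E interspersed among the
    consonants) instead of grouping them, giving the letter order
    A<F<G<H<B<J<I<K<C<S<T<M<O<P<D<Q<R<L<N<U<E<W<V<X<Y<Z in both case
    blocks; the '!'/'@' swap and '+-,.' rearrangement are kept.
    """
    return AlphabetOrdering(tuple(_letter_block_table(_IPCT_LETTERS)), "ipct")


def vowels_ordering(alphabet: Iterable[int] | None = None) -> AlphabetOrdering:
    """Vowels (aeiouAEIOU, in that order) first, rest in natural order.

    With no argument, an ordering over the full byte range is returned;
    otherwise only the given alphabet's symbols are used.
    """
    domain = sorted(alphabet) if alphabet is not None else list(range(256))
    present = set(domain)
    front = [v for v in VOWELS if v in present]
    rest = [s for s in domain if s not in set(VOWELS)]
    return AlphabetOrdering(tuple(front + rest), "vowels")


def random_ordering(
    alphabet: Iterable[int], seed: int | None = None,
    rng: random.Random | None = None,
) -> AlphabetOrdering:
    """Uniform random ordering by seeded Fisher-Yates shuffle."""
    if rng is None:
        if seed is None:
            raise ValueError("random ordering requires a seed or rng")
        rng = random.Random(seed)
        label = f"random[{seed}]"
    else:
        label = "random[rng]"
    return AlphabetOrdering(tuple(fisher_yates(sorted(alphabet), rng)), label)


def fda_ordering(
    alphabet: Iterable[int],
    partial_order: Iterable[tuple[int, int]],
    label: str = "fda",
) -> AlphabetOrdering:
    """Plugin hook: total ordering from an externally supplied partial order.

    The partial order (pairs ``(a, b)`` meaning a precedes b) is produced by
    an external algorithm; this function only completes it to a total order
    by topological sort, breaking ties by natural byte order so the result
    is deterministic.  Cycles raise ``ValueError``.
    """
    domain = sorted(alphabet)
    present = set(domain)
    succ: dict[int, set[int]] = {s: set() for s in domain}
    indeg = {s: 0 for s in domain}
    for a, b in partial_order:
        if a not in present or b not in present:
            raise ValueError(f"constraint ({a}, {b}) names symbol outside alphabet")
        if b not in succ[a]:
            succ[a].add(b)
            indeg[b] += 1
    heap = [s for s in domain if indeg[s] == 0]
    heapq.heapify(heap)
    out: list[int] = []
    while heap:
        s = heapq.heappop(heap)
        out.append(s)
        for t in sorted(succ[s]):
            indeg[t] -= 1
            if indeg[t] == 0:
                heapq.heappush(heap, t)
    if len(out) != len(domain):
        raise ValueError("partial order contains a cycle")
    return AlphabetOrdering(tuple(out), label)


#: Initialization methods selectable by name.
INIT_METHODS = (
    "random",
    "ascii",
    "first_appearance",
    "least_frequent",
    "most_frequent",
    "chapin_tate",
    "ipct",
    "vowels",
)


def init_ordering(
    text: str | bytes, method: str, seed: int | None = None
) -> AlphabetOrdering:
    """Build the named initialization ordering for ``text``.

    Full-byte orderings (chapin_tate, ipct, vowels) are restricted to the
    text's alphabet with relative order preserved.  ``seed`` is required
    for (and only used by) ``method="random"``.
    """
    alphabet = derive_alphabet(text)
    if method == "random":
        if seed is None:
            raise ValueError("random initialization requires a seed")
        return random_ordering(alphabet, seed)
    if method == "ascii":
        return ascii_ordering(text)
    if method == "first_appearance":
        return first_appearance_ordering(text)
    if method == "least_frequent":
        return least_frequent_ordering(text)
    if method == "most_frequent":
        return most_frequent_ordering(text)
    if method == "chapin_tate":
        return restrict(chapin_tate_ordering(), alphabet)
    if method == "ipct":
        return restrict(ipct_ordering(), alphabet)
    if method == "vowels":
        return restrict(vowels_ordering(), alphabet)
    raise ValueError(
        f"unknown initialization method {method!r}; choose from {INIT_METHODS}"
    )
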