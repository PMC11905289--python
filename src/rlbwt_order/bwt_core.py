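"""Burrows-Wheeler transforms under arbitrary alphabet orderings.

The BWT of a text is the last column of the row-sorted matrix of its cyclic
rotations; sorting is performed under a caller-supplied alphabet ordering
with the end-marker sentinel implicitly strictly least.  Two variants are
provided: ``bwt`` appends the sentinel (the form used for compression and
inversion) and ``bwt_star`` sorts the n rotations of the raw text without a
sentinel (the form used for run-count theory on cyclic strings).

Construction goes through a suffix array.  Texts are remapped to integer
ranks of the ordering with a dedicated sentinel rank strictly below all
others, so inputs using all 256 distinct bytes are supported; pass
``strict=True`` to refuse such inputs instead (the behaviour of tools that
reserve a real byte for the sentinel).

``naive_bwt`` sorts the rotations literally and serves as the testing
oracle for both fast paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AlphabetOrdering, as_bytes, derive_alphabet

__all__ = [
    "SENTINEL",
    "BWTResult",
    "suffix_array",
    "bwt",
    "bwt_star",
    "invert_bwt",
    "naive_bwt",
]

#: Symbol used for the end marker in transform outputs.  It is not a byte:
#: it compares below every symbol of every ordering.
SENTINEL = -1

#: Texts at or below this length use the plain comparison-sort suffix path;
#: longer texts use numpy prefix doubling.
_SMALL_N = 1024


@dataclass(frozen=True)
class BWTResult:
    """Last column of the sorted rotation matrix plus provenance.

    ``L`` holds symbols as ints; the sentinel (if present) is ``SENTINEL``.
    ``primary_index`` is the row of the original (sentinel-appended) string
    in the sorted matrix, i.e. the row whose suffix-array entry is 0; it is
    ``None`` for the sentinel-free variant.
    """

    L: tuple[int, ...]
    sentinel_used: bool
    ordering: AlphabetOrdering
    primary_index: int | None = None

    @property
    def ordering_label(self) -> str:
        return self.ordering.source_label

    def __len__(self) -> int:
        return len(self.L)

    def to_string(self, sentinel_char: str = "$") -> str:
        """Render L as a latin-1 string with ``sentinel_char`` for the marker."""
        return "".join(
            sentinel_char if s == SENTINEL else chr(s) for s in self.L
        )


def _rank_array(data: bytes, ordering: AlphabetOrdering) -> np.ndarray:
    """Map text bytes to ordering ranks (0-based); error on uncovered bytes."""
    present = set(data)
    if not ordering.covers(present):
        missing = sorted(present - set(ordering.symbols))
        raise ValueError(f"ordering does not cover text symbols {missing}")
    table = np.full(256, -1, dtype=np.int64)
    for k, s in enumerate(ordering.symbols):
        table[s] = k
    return table[np.frombuffer(data, dtype=np.uint8)]


def _sa_doubling(ranks: np.ndarray) -> np.ndarray:
    """Suffix array by Manber-Myers prefix doubling (numpy, O(n log^2 n))."""
    n = len(ranks)
    rank = ranks.copy()
    sa = np.argsort(rank, kind="stable")
    k = 1
    while k < n:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[:-k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new = np.cumsum(bump)
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = new
        if new[-1] == n - 1:
            break
        k *= 2
    return sa


def _sa_small(ranks: np.ndarray) -> list[int]:
    """Comparison sort of suffix slices; fast in C for short texts."""
    # ranks fit in a byte here (checked by caller), so compare as bytes.
    rb = bytes((ranks + 1).astype(np.uint8))
    return sorted(range(len(rb)), key=lambda i: rb[i:])


def suffix_array(
    text: str | bytes,
    ordering: AlphabetOrdering | None = None,
    strict: bool = False,
) -> list[int]:
    """Suffix array of ``text`` + sentinel under ``ordering``.

    Returns a permutation of 0..n: start positions of the n+1 suffixes of
    the sentinel-appended text in increasing order.  The sentinel-only
    suffix (position n) always sorts first.  ``ordering`` defaults to the
    natural byte order of the text's alphabet.

    With ``strict=True``, texts whose alphabet is all 256 bytes are
    refused (no byte left to act as the sentinel).
    """
    data = as_bytes(text)
    if not data:
        raise ValueError("cannot transform an empty text")
    if ordering is None:
        ordering = AlphabetOrdering(derive_alphabet(data), "ascii")
    if strict and len(set(data)) >= 256:
        raise ValueError(
            "strict mode: alphabet of 256 bytes leaves no sentinel byte"
        )
    # Shift ranks up by one and append sentinel rank 0: strictly least.
    ranks = np.concatenate([_rank_array(data, ordering) + 1, [0]])
    n = len(ranks)
    if n <= _SMALL_N and len(ordering) <= 254:
        return _sa_small(ranks)
    return [int(i) for i in _sa_doubling(ranks)]


def bwt(
    text: str | bytes,
    ordering: AlphabetOrdering | None = None,
    strict: bool = False,
) -> BWTResult:
    """Sentinel-appended BWT: L[i] = sentinel if SA[i]=0 else text[SA[i]-1]."""
    data = as_bytes(text)
    if ordering is None:
        ordering = AlphabetOrdering(derive_alphabet(data), "ascii")
    sa = suffix_array(data, ordering, strict=strict)
    L = tuple(SENTINEL if i == 0 else data[i - 1] for i in sa)
    return BWTResult(L, True, ordering, primary_index=sa.index(0))


def bwt_star(
    text: str | bytes, ordering: AlphabetOrdering | None = None
) -> BWTResult:
    """Sentinel-free cyclic BWT: last column over all n rotations.

    Duplicate rotations of non-primitive texts (u^k) are retained; equal
    rows are identical, so they sit adjacent in the sorted matrix.
    """
    data = as_bytes(text)
    if not data:
        raise ValueError("cannot transform an empty text")
    if ordering is None:
        ordering = AlphabetOrdering(derive_alphabet(data), "ascii")
    n = len(data)
    ranks = _rank_array(data, ordering)
    if n <= _SMALL_N // 2 and len(ordering) <= 255:
        rb = bytes(ranks.astype(np.uint8))
        dd = rb + rb
        order = sorted(range(n), key=lambda i: dd[i : i + n])
    else:
        # Suffixes of the doubled text, restricted to starts < n, sort the
        # rotations: each such suffix begins with the full rotation, and
        # ties beyond it only occur between identical rotations.
        doubled = np.concatenate([ranks + 1, ranks + 1, [0]])
        sa = _sa_doubling(doubled)
        order = [int(i) for i in sa if i < n]
    L = tuple(data[(i + n - 1) % n] for i in order)
    return BWTResult(L, False, ordering)


def invert_bwt(result: BWTResult) -> bytes:
    """Recover the original text from a sentinel-bearing BWT via LF mapping."""
    if not result.sentinel_used:
        raise ValueError("inversion requires the sentinel-appended transform")
    L = result.L
    if L.count(SENTINEL) != 1:
        raise ValueError("malformed transform: expected exactly one sentinel")
    rank_of = {s: k + 1 for k, s in enumerate(result.ordering.symbols)}
    rank_of[SENTINEL] = 0
    try:
        keys = [rank_of[s] for s in L]
    except KeyError as exc:
        raise ValueError(f"symbol {exc} not covered by the ordering") from exc
    m = len(L)
    # C[k] = number of symbols with rank < k; occ = running count per symbol.
    counts = [0] * (len(rank_of) + 1)
    for k in keys:
        counts[k + 1] += 1
    C = list(np.cumsum(counts[:-1]))
    occ = [0] * len(rank_of)
    LF = [0] * m
    for i, k in enumerate(keys):
        LF[i] = C[k] + occ[k]
        occ[k] += 1
    # Row 0 is the rotation starting with the sentinel; walking LF from it
    # reads the text right to left.
    out = bytearray()
    row = 0
    for _ in range(m - 1):
        out.append(L[row])
        row = LF[row]
    return bytes(reversed(out))


def naive_bwt(
    text: str | bytes,
    ordering: AlphabetOrdering | None = None,
    with_sentinel: bool = True,
    cap: int = 4096,
) -> BWTResult:
    """Oracle transform: materialize and sort all rotations.

    Literal implementation of the rotation-matrix definition, kept
    independent of the suffix-array paths so it can certify them.  Refuses
    texts longer than ``cap``.
    """
    data = as_bytes(text)
    if not data:
        raise ValueError("cannot transform an empty text")
    if len(data) > cap:
        raise ValueError(f"oracle cap exceeded: n={len(data)} > {cap}")
    if ordering is None:
        ordering = AlphabetOrdering(derive_alphabet(data), "ascii")
    if not ordering.covers(set(data)):
        raise ValueError("ordering does not cover text symbols")
    rank_of = {s: k + 1 for k, s in enumerate(ordering.symbols)}
    rank_of[SENTINEL] = 0
    seq = list(data) + [SENTINEL] if with_sentinel else list(data)
    m = len(seq)
    rotations = sorted(
        range(m), key=lambda i: [rank_of[seq[(i + d) % m]] for d in range(m)]
    )
    L = tuple(seq[(i + m - 1) % m] for i in rotations)
    primary = rotations.index(0) if with_sentinel else None
    return BWTResult(L, with_sentinel, ordering, primary_index=primary)
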