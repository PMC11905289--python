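"""Run-length encoding and the byte-pair size measure.

A run is a maximal substring of identical symbols; the run-length encoding
of a sequence is its unique maximal-run decomposition.  For size accounting
each run is stored as byte pairs (symbol, length): a length byte holds at
most 255, so a run of length l costs 2*ceil(l/255) bytes.  The number of
runs in a BWT output is the r value central to run-length compressed
indexes (the r-index stores the text in O(r) space).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Hashable, Iterable, Sequence

__all__ = ["RLEString", "runs", "decode", "encoded_size", "r_value", "byte_pairs"]

#: Largest run length representable by a single length byte.
MAX_RUN_BYTE = 255


@dataclass(frozen=True)
class RLEString:
    """Maximal-run decomposition: (symbol, length) pairs, lengths >= 1.

    Adjacent runs carry distinct symbols and lengths sum to the source
    sequence length.
    """

    runs: tuple[tuple[Hashable, int], ...]

    def __post_init__(self) -> None:
        for sym, length in self.runs:
            if length < 1:
                raise ValueError("run lengths must be positive")
        for (a, _), (b, _) in zip(self.runs, self.runs[1:]):
            if a == b:
                raise ValueError("adjacent runs must have distinct symbols")

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.runs)


def runs(seq: Sequence[Hashable] | str | bytes) -> RLEString:
    """Maximal-run decomposition of ``seq`` (empty input gives zero runs)."""
    return RLEString(
        tuple((sym, sum(1 for _ in grp)) for sym, grp in groupby(seq))
    )


def decode(rle: RLEString) -> list:
    """Inverse of :func:`runs`: expand runs back to the flat sequence."""
    out: list = []
    for sym, length in rle.runs:
        out.extend([sym] * length)
    return out


def r_value(rle: RLEString) -> int:
    """Number of maximal runs (the r statistic)."""
    return len(rle.runs)


def encoded_size(rle: RLEString) -> int:
    """Byte-pair encoded size: 2 * sum over runs of ceil(length/255)."""
    return 2 * sum(-(-length // MAX_RUN_BYTE) for _, length in rle.runs)


def byte_pairs(rle: RLEString) -> list[tuple[Hashable, int]]:
    """The encoded pair stream: each run split into (symbol, 255)* plus a
    remainder pair, ceil(length/255) pairs in total."""
    out: list[tuple[Hashable, int]] = []
    for sym, length in rle.runs:
        full, rem = divmod(length, MAX_RUN_BYTE)
        out.extend([(sym, MAX_RUN_BYTE)] * full)
        if rem:
            out.append((sym, rem))
    return out
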