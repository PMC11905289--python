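"""Move operators and neighbor enumeration over alphabet orderings.

Two standard permutation operators are supported.  Swap exchanges the
symbols at positions i < j, giving sigma*(sigma-1)/2 neighbors.  Insert
removes the symbol at position i and reinserts it at position j (i != j),
shifting the interval between them, giving sigma*(sigma-1) neighbors; the
(i, i+1) and (i+1, i) moves produce the same ordering and are deliberately
retained, so every enumerated neighbor costs one objective evaluation.

Each operator's move list can be walked in lexicographic order (swap pairs
(0,1), (0,2), ..., (sigma-2, sigma-1); insert pairs row-major over (i, j)),
in the exact reverse of that order, or in a freshly shuffled random order.
Two-operator specs stage one operator's complete enumeration before the
other's.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterator

from .alphabet import AlphabetOrdering, fisher_yates

__all__ = [
    "Move",
    "NeighborhoodSpec",
    "apply_move",
    "swap_moves",
    "insert_moves",
    "swap_neighbors",
    "insert_neighbors",
    "combined_neighbors",
    "neighbors",
]

_ORDERS = ("lex", "revlex", "random")


@dataclass(frozen=True)
class Move:
    """One elementary move: kind in {"swap", "insert"}, index pair (i, j)."""

    kind: str
    i: int
    j: int


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Which operators to enumerate, in which order.

    ``operators`` holds one or two distinct names from {"swap", "insert"};
    with two, the first is exhausted before the second on every pass.
    ``order`` is "lex", "revlex" or "random"; random enumeration draws a
    fresh shuffle per pass from the supplied rng (seeded by ``seed`` when
    the caller does not pass one).
    """

    operators: tuple[str, ...]
    order: str = "lex"
    seed: int | None = None

    def __post_init__(self) -> None:
        ops = tuple(self.operators)
        if not ops or len(ops) > 2 or len(set(ops)) != len(ops):
            raise ValueError("operators must be 1 or 2 distinct names")
        for op in ops:
            if op not in ("swap", "insert"):
                raise ValueError(f"unknown operator {op!r}")
        if self.order not in _ORDERS:
            raise ValueError(f"order must be one of {_ORDERS}")
        object.__setattr__(self, "operators", ops)


def swap_moves(sigma: int) -> list[Move]:
    """Swap index pairs in lexicographic order; empty when sigma < 2."""
    return [
        Move("swap", i, j) for i in range(sigma) for j in range(i + 1, sigma)
    ]


def insert_moves(sigma: int) -> list[Move]:
    """Insert index pairs, row-major over (i, j) with i != j."""
    return [
        Move("insert", i, j)
        for i in range(sigma)
        for j in range(sigma)
        if i != j
    ]


def apply_move(ordering: AlphabetOrdering, move: Move) -> AlphabetOrdering:
    """Return the neighbor ordering reached by ``move``."""
    syms = list(ordering.symbols)
    if move.kind == "swap":
        syms[move.i], syms[move.j] = syms[move.j], syms[move.i]
    elif move.kind == "insert":
        sym = syms.pop(move.i)
        syms.insert(move.j, sym)
    else:
        raise ValueError(f"unknown move kind {move.kind!r}")
    return AlphabetOrdering(tuple(syms), ordering.source_label)


def _arrange(
    moves: list[Move], order: str, rng: random.Random | None
) -> list[Move]:
    if order == "lex":
        return moves
    if order == "revlex":
        return moves[::-1]
    if order == "random":
        if rng is None:
            raise ValueError("random enumeration order requires an rng")
        idx = fisher_yates(range(len(moves)), rng)
        return [moves[k] for k in idx]
    raise ValueError(f"unknown enumeration order {order!r}")


def _operator_moves(op: str, sigma: int) -> list[Move]:
    return swap_moves(sigma) if op == "swap" else insert_moves(sigma)


def swap_neighbors(
    ordering: AlphabetOrdering,
    order: str = "lex",
    rng: random.Random | None = None,
) -> Iterator[tuple[Move, AlphabetOrdering]]:
    """Lazily yield all swap neighbors of ``ordering``."""
    for move in _arrange(swap_moves(len(ordering)), order, rng):
        yield move, apply_move(ordering, move)


def insert_neighbors(
    ordering: AlphabetOrdering,
    order: str = "lex",
    rng: random.Random | None = None,
) -> Iterator[tuple[Move, AlphabetOrdering]]:
    """Lazily yield all insert neighbors of ``ordering``."""
    for move in _arrange(insert_moves(len(ordering)), order, rng):
        yield move, apply_move(ordering, move)


def combined_neighbors(
    ordering: AlphabetOrdering,
    spec: NeighborhoodSpec,
    rng: random.Random | None = None,
) -> Iterator[tuple[Move, AlphabetOrdering]]:
    """Staged enumeration: first operator's moves, then the second's.

    Each stage is arranged in ``spec.order`` independently; with random
    order the shuffles consume the rng in stage order, so a pass is
    reproducible from the rng state.
    """
    for op in spec.operators:
        for move in _arrange(_operator_moves(op, len(ordering)), spec.order, rng):
            yield move, apply_move(ordering, move)


def neighbors(
    ordering: AlphabetOrdering,
    spec: NeighborhoodSpec,
    rng: random.Random | None = None,
) -> Iterator[tuple[Move, AlphabetOrdering]]:
    """One full enumeration pass of ``spec`` around ``ordering``."""
    if spec.order == "random" and rng is None:
        rng = random.Random(spec.seed)
    yield from combined_neighbors(ordering, spec, rng)
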