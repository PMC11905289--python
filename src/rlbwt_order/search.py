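"""Search strategies over the space of alphabet orderings.

The search space for an alphabet of size sigma holds sigma! orderings and
minimizing the RLE-BWT size over it is computationally hard, so three
complementary strategies are provided:

* uniform random sampling (Fisher-Yates draws) as a baseline, together
  with the harmonic-sum upper bound on its expected number of best-so-far
  improvements;
* exhaustive enumeration for small alphabets (e.g. the 24 orderings of a
  4-letter genomic alphabet);
* first-improvement local search: scan the configured neighborhood in a
  fixed or shuffled order, adopt the first strictly better neighbor, and
  repeat until a complete scan proves a local optimum or a step budget is
  exhausted.

One "step" is one objective evaluation; the initialization's own
evaluation is step 0 and improvements are recorded with the step index at
which they were found (their hitting time).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np

from .alphabet import (
    AlphabetOrdering,
    as_bytes,
    derive_alphabet,
    init_ordering,
    random_ordering,
)
from .fitness import fitness, percent_change
from .neighborhoods import Move, NeighborhoodSpec, apply_move, neighbors
from .neighborhoods import _arrange, _operator_moves  # pass-level enumeration

__all__ = [
    "SearchConfig",
    "SearchTrace",
    "SearchResult",
    "first_improvement_search",
    "random_sampling",
    "RandomSamplingResult",
    "expected_updates_bound",
    "expected_updates_log",
    "exhaustive_search",
    "ExhaustiveResult",
    "summarize_samples",
    "SampleSummary",
    "random_init_seeds",
]


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of one first-improvement run.

    ``init`` is an initialization method name (see ``INIT_METHODS``) or a
    ready-made ordering (e.g. from the partial-order plugin); ``init_seed``
    is required for the random method.  ``strategy`` selects what happens
    after an accepted move: "restart" begins a fresh pass at the first
    neighbor of the first operator (the canonical first-improvement
    reading), "continue" keeps walking the remaining move list against the
    new incumbent.
    """

    init: str | AlphabetOrdering = "ascii"
    init_seed: int | None = None
    neighborhood: NeighborhoodSpec = field(
        default_factory=lambda: NeighborhoodSpec(("swap",), "lex")
    )
    max_steps: int | None = None
    record_trace: bool = True
    strategy: str = "restart"

    def __post_init__(self) -> None:
        if self.max_steps is not None and self.max_steps < 1:
            raise ValueError("max_steps must be >= 1 when set")
        if self.strategy not in ("restart", "continue"):
            raise ValueError("strategy must be 'restart' or 'continue'")


@dataclass
class SearchTrace:
    """Step-by-step record of a run.

    ``improvements`` holds (hitting time, fitness) for each accepted move;
    fitness values strictly decrease and hitting times strictly increase.
    ``steps`` counts neighbor evaluations (the initialization evaluation is
    step 0 and excluded).
    """

    steps: int = 0
    initial_fitness: int = 0
    improvements: list[tuple[int, int]] = field(default_factory=list)
    terminated_by: str = "local_optimum"


@dataclass(frozen=True)
class SearchResult:
    """Final ordering with its fitness and local-optimality certificate.

    ``certificate`` is True only when a complete scan of the configured
    neighborhood at ``best_ordering`` found no strictly better neighbor.
    """

    best_ordering: AlphabetOrdering
    best_fitness: int
    percent_change: float
    certificate: bool


def _resolve_init(
    text: bytes, config: SearchConfig
) -> AlphabetOrdering:
    if isinstance(config.init, AlphabetOrdering):
        return config.init
    return init_ordering(text, config.init, config.init_seed)


def first_improvement_search(
    text: str | bytes, config: SearchConfig
) -> tuple[SearchResult, SearchTrace]:
    """First-improvement local search over alphabet orderings.

    Starting from the configured initialization, repeatedly enumerate the
    neighborhood in the configured order and adopt the first neighbor with
    strictly smaller fitness (ties are rejected; strictness prevents
    cycling).  With two operators the second is consulted only after the
    first's enumeration is exhausted without improvement, and an accepted
    move returns control to the first operator.  The run terminates when a
    complete pass finds no improvement (certified local optimum) or when
    the step budget is hit (no certificate).
    """
    data = as_bytes(text)
    if not data:
        raise ValueError("empty text")
    spec = config.neighborhood
    rng = random.Random(spec.seed) if spec.order == "random" else None

    current = _resolve_init(data, config)
    current_fit = fitness(data, current)  # step 0, not an improvement
    trace = SearchTrace(steps=0, initial_fitness=current_fit)
    terminated_by = None

    while terminated_by is None:
        improved = False
        # One pass: the full staged move list against the incumbent.  Under
        # the "continue" strategy an accepted move keeps consuming this
        # list (recomputed against the new incumbent); under "restart" the
        # pass is abandoned and a fresh one begins.
        pass_moves: list[Move] = []
        for op in spec.operators:
            pass_moves.extend(
                _arrange(_operator_moves(op, len(current)), spec.order, rng)
            )
        for move in pass_moves:
            if config.max_steps is not None and trace.steps >= config.max_steps:
                terminated_by = "step_budget"
                break
            candidate = apply_move(current, move)
            cand_fit = fitness(data, candidate)
            trace.steps += 1
            if cand_fit < current_fit:
                current, current_fit = candidate, cand_fit
                improved = True
                if config.record_trace:
                    trace.improvements.append((trace.steps, cand_fit))
                if config.strategy == "restart":
                    break
        if terminated_by is None and not improved:
            terminated_by = "local_optimum"

    trace.terminated_by = terminated_by
    result = SearchResult(
        best_ordering=current,
        best_fitness=current_fit,
        percent_change=percent_change(current_fit, len(data)),
        certificate=terminated_by == "local_optimum",
    )
    return result, trace


# ---------------------------------------------------------------------------
# Random sampling baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomSamplingResult:
    """Best ordering seen, its fitness, and the update (improvement) count."""

    best_ordering: AlphabetOrdering
    best_fitness: int
    updates: int
    trials: int
    samples: tuple[int, ...] | None = None


def random_sampling(
    text: str | bytes,
    trials: int,
    seed: int,
    keep_samples: bool = False,
) -> RandomSamplingResult:
    """Uniform random sampling of orderings, tracking the running best.

    Each trial draws an independent Fisher-Yates shuffle of the alphabet;
    the first sample always counts as an update and subsequent samples
    count only on strict improvement (ties are not improvements).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    data = as_bytes(text)
    alphabet = derive_alphabet(data)
    rng = random.Random(seed)
    best: AlphabetOrdering | None = None
    best_fit = 0
    updates = 0
    samples: list[int] = []
    for _ in range(trials):
        ordering = random_ordering(alphabet, rng=rng)
        fit = fitness(data, ordering)
        if keep_samples:
            samples.append(fit)
        if best is None or fit < best_fit:
            best, best_fit = ordering, fit
            updates += 1
    assert best is not None
    return RandomSamplingResult(
        best, best_fit, updates, trials,
        tuple(samples) if keep_samples else None,
    )


def expected_updates_bound(trials: int) -> float:
    """Harmonic upper bound on the expected number of sampling updates.

    With every new sample independent of the past and all fitness values
    distinct, the chance that sample T+1 improves on the best of the first
    T is 1/(T+1); summing gives sum_{i=0..trials} 1/(i+1), the harmonic
    number H_{trials+1}.  Because real fitness values collide (ties are not
    improvements), the true expectation is below this bound.
    """
    if trials < 0:
        raise ValueError("trials must be >= 0")
    return float(np.sum(1.0 / np.arange(1, trials + 2)))


def expected_updates_log(trials: int) -> float:
    """Natural-log asymptotic form of the sampling-updates bound, ln(trials).

    The harmonic bound grows as O(log T); this is the logarithmic value
    commonly tabulated for large T (about 12.38 at T = 240,000).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    return math.log(trials)


def random_init_seeds(master_seed: int, count: int = 20) -> list[int]:
    """Derive ``count`` sub-seeds for the shared random initial orderings.

    The same derived seeds (hence the same starting orderings) are reused
    across every configuration of an experiment so that neighborhood
    effects are compared on identical starting points.
    """
    rng = random.Random(master_seed)
    return [rng.randrange(2**31) for _ in range(count)]


# ---------------------------------------------------------------------------
# Exhaustive search (small alphabets) and sample summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSummary:
    """Min/max/mean/std of percentage change over a fitness collection."""

    min_percent: float
    max_percent: float
    mean_percent: float
    std_percent: float


def summarize_samples(
    fitnesses: Sequence[int], uncompressed: int
) -> SampleSummary:
    """Summary statistics of percent change for a list of fitness values.

    Std is the sample standard deviation (ddof=1); a single value has
    std 0 by convention.
    """
    if len(fitnesses) == 0:
        raise ValueError("empty fitness list")
    pc = np.array([percent_change(f, uncompressed) for f in fitnesses])
    std = float(np.std(pc, ddof=1)) if len(pc) > 1 else 0.0
    return SampleSummary(
        float(pc.min()), float(pc.max()), float(pc.mean()), std
    )


@dataclass(frozen=True)
class ExhaustiveResult:
    """Every ordering of a small alphabet with its fitness."""

    best_ordering: AlphabetOrdering
    best_fitness: int
    worst_ordering: AlphabetOrdering
    worst_fitness: int
    table: tuple[tuple[AlphabetOrdering, int], ...]
    summary: SampleSummary


def exhaustive_search(
    text: str | bytes, permutation_budget: int = 40320
) -> ExhaustiveResult:
    """Evaluate every permutation of the text's alphabet.

    Feasible only for small alphabets (sigma! orderings; a 4-letter
    genomic alphabet gives 24).  Refuses when sigma! exceeds
    ``permutation_budget`` — raise the budget explicitly, or use
    :func:`first_improvement_search` / :func:`random_sampling` instead.
    Ties for best/worst are broken by enumeration order (first wins).
    """
    data = as_bytes(text)
    alphabet = derive_alphabet(data)
    total = math.factorial(len(alphabet))
    if total > permutation_budget:
        raise ValueError(
            f"sigma={len(alphabet)} gives {total} orderings, exceeding the "
            f"budget of {permutation_budget}; use local search or sampling "
            "for alphabets this large"
        )
    table: list[tuple[AlphabetOrdering, int]] = []
    for perm in permutations(alphabet):
        ordering = AlphabetOrdering(perm, "exhaustive")
        table.append((ordering, fitness(data, ordering)))
    fits = [f for _, f in table]
    best_i = min(range(len(table)), key=lambda i: fits[i])
    worst_i = max(range(len(table)), key=lambda i: fits[i])
    return ExhaustiveResult(
        table[best_i][0], table[best_i][1],
        table[worst_i][0], table[worst_i][1],
        tuple(table),
        summarize_samples(fits, len(data)),
    )
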