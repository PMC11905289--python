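"""Worked-example registry and synthetic text generators.

The registry pins the small strings whose transforms are known by hand
(desk-checkable rotations) so every module can be regression-tested
without external data; the generators produce seeded random texts with
controlled alphabet size and run structure for property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .alphabet import AlphabetOrdering

__all__ = ["WorkedExample", "paper_examples", "random_text", "power_text"]


@dataclass(frozen=True)
class WorkedExample:
    """One hand-verifiable transform: input, ordering, expected outputs.

    ``expected_bwt`` is the sentinel-appended transform ('$' marks the
    sentinel) and ``expected_bwt_star`` the sentinel-free cyclic one;
    either may be None when the example only fixes the other.  ``citation``
    is a short tag naming the example within the registry.
    """

    text: str
    ordering: AlphabetOrdering
    expected_bwt: str | None = None
    expected_bwt_star: str | None = None
    expected_size: int | None = None
    expected_r_star: int | None = None
    citation: str = ""


def _ord(s: str) -> AlphabetOrdering:
    return AlphabetOrdering.from_string(s, s)


def paper_examples() -> list[WorkedExample]:
    """The registry of desk-checked worked examples.

    Includes both orderings of the reversal-symmetry pairs (aabbcc and the
    non-primitive abcabc), whose sentinel-free transforms have equal run
    counts under an ordering and its reverse.
    """
    return [
        WorkedExample(
            "cacatcg", _ord("acgt"),
            expected_bwt="gcc$atca", expected_size=14,
            citation="cacatcg-natural",
        ),
        WorkedExample(
            "cacatcg", _ord("agct"),
            expected_bwt="gccc$ata", expected_size=12,
            citation="cacatcg-reordered",
        ),
        WorkedExample(
            "mississippi", _ord("imps"),
            expected_bwt="ipssm$pissii",
            citation="mississippi-natural",
        ),
        WorkedExample(
            "aabbcc", _ord("abc"),
            expected_bwt_star="caabcb", expected_r_star=5,
            citation="ternary-primitive",
        ),
        WorkedExample(
            "aabbcc", _ord("cba"),
            expected_bwt_star="bcbaac", expected_r_star=5,
            citation="ternary-primitive-reversed",
        ),
        WorkedExample(
            "abcabc", _ord("abc"),
            expected_bwt_star="ccaabb", expected_r_star=3,
            citation="ternary-nonprimitive",
        ),
        WorkedExample(
            "abcabc", _ord("cba"),
            expected_bwt_star="bbaacc", expected_r_star=3,
            citation="ternary-nonprimitive-reversed",
        ),
        WorkedExample(
            "acacacbbacbac", _ord("abc"),
            expected_bwt_star="bccbccbcaaaaa", expected_r_star=7,
            citation="ternary-run-count",
        ),
    ]


def _default_alphabet(sigma: int) -> list[int]:
    if sigma < 1 or sigma > 256:
        raise ValueError("alphabet size must be in 1..256")
    if sigma <= 26:
        return [ord("a") + k for k in range(sigma)]
    return list(range(sigma))


def random_text(
    n: int,
    sigma: int,
    model: str = "iid",
    seed: int = 0,
    persistence: float = 0.9,
) -> bytes:
    """Seeded random text over exactly ``sigma`` distinct symbols.

    Models: "iid" draws symbols uniformly; "markov" repeats the previous
    symbol with probability ``persistence`` (tuning run structure — high
    persistence means long runs); "power_law" draws symbol k with weight
    1/(k+1).  Coverage of all sigma symbols is enforced (rejection with a
    deterministic fallback overwrite), so ``n >= sigma`` is required.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma > n:
        raise ValueError("cannot cover sigma symbols with fewer positions")
    alphabet = _default_alphabet(sigma)
    rng = random.Random(seed)

    def draw() -> list[int]:
        if model == "iid":
            return [rng.choice(alphabet) for _ in range(n)]
        if model == "power_law":
            weights = [1.0 / (k + 1) for k in range(sigma)]
            return rng.choices(alphabet, weights=weights, k=n)
        if model == "markov":
            out = [rng.choice(alphabet)]
            for _ in range(n - 1):
                if rng.random() < persistence:
                    out.append(out[-1])
                else:
                    out.append(rng.choice(alphabet))
            return out
        raise ValueError(f"unknown model {model!r}")

    for _ in range(50):
        symbols = draw()
        if len(set(symbols)) == sigma:
            return bytes(symbols)
    # Force coverage: overwrite sigma positions with a shuffled alphabet.
    positions = sorted(rng.sample(range(n), sigma))
    filler = list(alphabet)
    rng.shuffle(filler)
    for pos, sym in zip(positions, filler):
        symbols[pos] = sym
    return bytes(symbols)


def power_text(u: str | bytes, k: int) -> bytes:
    """The k-fold repetition u^k (non-primitive for k > 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    data = u.encode("latin-1") if isinstance(u, str) else bytes(u)
    if not data:
        raise ValueError("u must be non-empty")
    return data * k
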