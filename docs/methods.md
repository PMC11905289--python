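# Methods

## Model

A text is a byte sequence read verbatim from a file; its alphabet is the
set of distinct bytes (σ ≤ 256), and an alphabet ordering is a permutation
of that set.  The end-marker sentinel is not a byte: internally every byte
is mapped to its rank under the ordering, shifted up by one, and the
sentinel takes rank 0, strictly least.  This makes inputs that use all 256
distinct bytes transformable; a `strict` flag reproduces the refusal
behaviour of implementations that must reserve a real byte for the marker.

Two transforms are computed.  The sentinel-appended BWT is read off the
suffix array of s·$: `L[i] = $ if SA[i]=0 else s[SA[i]−1]`; it is
invertible by the last-first mapping and is the form the objective
function uses.  The sentinel-free cyclic transform sorts all n rotations
of the raw text; duplicate rotations of non-primitive texts u^k are
retained (identical rows are necessarily adjacent).  It is the form for
which reversing the ordering provably preserves the run count, and the
suite asserts that symmetry empirically on binary/ternary and u^k texts.

The objective is the byte-pair RLE size: each maximal run costs
2·⌈length/255⌉ bytes (a symbol byte plus length bytes capped at 255).  The
sentinel's run is included in the compressed size; the uncompressed size
is the raw text length.  Run count r is reported as a statistic but never
optimized — memory, not run count, is the quantity of interest, and the
two disagree once runs exceed 255.

## Suffix array construction

Texts up to 1024 bytes (and σ ≤ 254) are sorted by direct comparison of
suffix slices of the rank-translated byte string — C-speed comparisons,
fastest at the sizes the search evaluates millions of times.  Longer texts
use Manber–Myers prefix doubling on numpy arrays (O(n log² n)).  The
cyclic transform sorts rotation starts via the doubled text's suffixes.
Correctness of every path is defined by `naive_bwt`, an independent oracle
that literally materializes and sorts the rotation matrix; the property
suite cross-checks 1,000 random texts (n ≤ 200, σ ≤ 8) per run, and the
acceptance script re-runs a seeded 50-instance cross-check before
reporting anything.

## Search

First-improvement local search scans one full enumeration pass of the
configured neighborhood around the incumbent and accepts the first
strictly better neighbor (ties rejected — strictness prevents cycling).
Operators: Swap over index pairs (0,1), (0,2), …, (σ−2,σ−1); Insert over
ordered pairs (i,j), i≠j, row-major, where the symbol at i is removed and
reinserted at j.  Insert's adjacent-transposition duplicates ((i,i+1) vs
(i+1,i)) are retained, so a pass costs exactly σ(σ−1) evaluations.
Enumeration order is lex, revlex (its exact reverse), or a fresh
Fisher–Yates shuffle per pass (the neighbor list changes with the
incumbent, so re-shuffling per pass is the natural reading).  With two
operators the first is exhausted before the second and an accepted move
returns control to the first operator.

After an accepted move the default strategy restarts the pass at the first
neighbor (the canonical first-improvement protocol); a `continue` strategy
that keeps consuming the current move list against the new incumbent is
provided as a sensitivity switch, since published step counts are
sensitive to this unstated choice.  A run terminates with a certificate
only when a complete pass finds no improvement; budgeted runs report
`step_budget` and carry no certificate.  One step = one objective
evaluation; the initialization's own evaluation is step 0 and is not an
improvement; improvements are recorded at the evaluation index that found
them (hitting time).

Random sampling draws independent Fisher–Yates shuffles and counts
best-so-far updates (the first draw always counts; ties do not).  With
distinct fitness values the expected update count after T samples is
bounded by the harmonic sum Σ_{i=0..T} 1/(i+1) = H_{T+1}; because real
fitness values collide, the truth lies below it.  `expected_updates_bound`
returns the exact sum (12.9656 at T = 240,000); `expected_updates_log`
returns the ln T asymptotic form often tabulated for large T (12.3884 at
T = 240,000 — note ln T omits the Euler–Mascheroni constant, which is why
it sits visibly below the exact sum).  The Monte-Carlo test compares the
mean of 200 independent 1,000-trial repetitions against the exact bound
within three standard errors.

Exhaustive enumeration walks all σ! permutations (refused above a
40,320-permutation budget, i.e. σ > 8 by default) and reports the
best/worst orderings with a min/max/mean/std summary of percentage change.
Summary std is the sample standard deviation (ddof = 1; a single value
reports 0).

## Initializations

ASCII, first appearance, least/most frequent (frequency ties broken by
natural byte order, keeping the methods deterministic), Chapin–Tate, its
inverse permutation, vowels-first, and seeded random shuffles; a plugin
hook accepts an externally computed partial order and completes it by
topological sort with natural-byte tie-breaking.  The Chapin–Tate table is
built over all 256 bytes from its textual description: '!'/'@' swapped,
'+,-.' rearranged to '+-,.', vowels AEIOU/aeiou moved to the front of each
case block, consonants reordered B<C<D<G<F<H<R<L<S<M<N<P<Q<J<K<T<W<V<X<Y<Z,
all unmentioned bytes keeping natural relative order — punctuation beyond
the two documented changes is an assumption of this package.  The inverse
permutation applies to the letter blocks (giving A<F<G<H<B<J<I<K<C<S<T<M<
O<P<D<Q<R<L<N<U<E<W<V<X<Y<Z, vowels interspersed as A<I<O<U<E) and keeps
the punctuation changes.  Full-byte orderings are restricted to a concrete
text's alphabet preserving relative order.  Experiments that compare
configurations on random starts derive a fixed set of sub-seeds from one
master seed (`random_init_seeds`) so all configurations share identical
starting orderings.

## Synthetic data

`random_text(n, σ, model, seed)` generates seeded texts with exactly σ
distinct symbols: iid uniform, a persistence-parameterized Markov chain
(persistence p repeats the previous symbol, tuning run structure; default
0.9), and a 1/(k+1) power-law symbol distribution.  Coverage of all σ
symbols is enforced (rejection sampling with a deterministic overwrite
fallback).  `power_text(u, k)` builds non-primitive u^k inputs.  These
emulate the size/alphabet regimes of real inputs but not their long-range
structure (natural-language morphology, executable sections, fax-image
bit patterns), so passing tests demonstrate algorithmic correctness and
the qualitative search behaviour — sampling distributions, improvement
traces, certificate validity — not the specific compression percentages
achievable on any real corpus.  Property and consistency tests run on
texts of n ≈ 24–400 and σ ≈ 2–16, sizes at which exhaustive or oracle
verification stays cheap; nothing in the method depends on those sizes.

## Numerical and edge-case choices

Unary texts transform to themselves and every ordering is equivalent
(fitness 4: one symbol run plus the sentinel pair).  Empty texts are
rejected everywhere.  Fitness is bounded by 2 ≤ fitness ≤ 2(n+1) and
depends only on symbol ranks, not byte identities.  Best/worst ties in
exhaustive search are broken by enumeration order (first wins).  The
ordering-spec file format is one two-digit hex byte per line, '#'
comments; FASTA input concatenates records with headers and newlines
stripped and sequence case-folded to lower by default (switchable), since
genomic alphabets are conventionally lower-case single-case.

## Limitations

Local search certifies only local optimality under the configured
neighborhood; no approximation guarantee exists (the underlying problem is
APX-hard).  Published per-file step counts from other implementations may
not reproduce bit-exactly because the restart-vs-continue protocol and the
Insert enumeration order are rarely stated; both are explicit switches
here.  Alternative RLE codecs (varint lengths, bit-packing) and block-move
or crossover operators are out of scope.
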