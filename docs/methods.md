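# Methods

## Seeds, alignments and the hit automaton

Alignments are gapless and binary: `1` for a match, `0` for a mismatch.  A
seed is canonical when it starts and ends with `1`; leading/trailing
don't-cares only shift the hit set, so canonical form is enforced at parse
time and the enumeration classes "weight w, span ≤ s" are taken over
canonical patterns (for w ≥ 2 there are Σ_s C(s−2, w−2) of them).
Positions are 1-based.

The *at-least-one-hit* DFA of a seed set is built by a subset construction
over compatible prefix lengths: a state records, per seed, every prefix
length of that seed consistent with the input suffix read so far (prefix
length 0 is implicitly always active, since a hit may start anywhere);
completing any seed's span moves to a single absorbing final state.  This
yields the O(w·2^(s−w)) state bound per seed directly and handles multiple
seeds by synchronized subsets over the union language.  Minimization is
Moore partition refinement (signature hashing per round); the contract is
minimality and language equivalence, and states are renumbered in
breadth-first order so that serialized automata are reproducible.  Because
all final states are merged into one absorbing sink, "once hit, always hit"
holds structurally and acceptance totals are monotone in ℓ.

The intersection product with the (ℓ+1)-state match-counting automaton is
built lazily and breadth-first, so pairs unreachable within ℓ symbols — for
example (ℓ−1, initial) for the seed `101`, which would need two mismatches
after the last reset — are never materialized.

## Counting DP and exact arithmetic

The coefficient vector c(π, m) is computed by one pass of the counting
semi-ring (ℕ, +, ×): each DFA state carries a list of counts indexed by the
number of matches read, updated per step; final-state totals per m are the
coefficients.  Counts are unbounded Python integers, removing any word-size
restriction (at ℓ = 64 with multiple seeds the per-state totals can exceed
64 bits).  The DP object is incremental: advancing from ℓ to ℓ′ reuses the
state and is bit-identical to a fresh run — this is what the per-length
pipeline uses.  Two invariants are enforced in tests: per-step conservation
(totals over all states at step i per match count equal C(i, m)) and
equivalence with a bit-parallel 2^ℓ brute-force oracle (capped at ℓ = 16).

All model values are exact rationals (`fractions.Fraction`): coefficients
are integers, parameters are accepted as rationals, and float parameters
are lifted to their exact binary value before evaluation, because the
Bernoulli polynomial mixes very large coefficients with very small
monomials and naive floating-point summation is unreliable.  Floats appear
only on explicit conversion for display.

The monomial integral ∫ p^u (1−p)^v dp is evaluated by binomial expansion
of (1−p)^v — an exact antiderivative — so each (ℓ, p_a, p_b) table is
computed once, independently of the seed, and shared by a whole candidate
set.

## Losslessness

Two independent routes are implemented and cross-checked: the tropical
(min, +) DP over the hit DFA ('0'-transitions cost one mismatch) and the
binomial tail equality c(π, m) = C(ℓ, m) for all m ≥ ℓ−k.  On failure the
tropical route reconstructs a witness: a backward layer of minimal suffix
costs is computed first, then the forward greedy walk always prefers `0`,
which yields the lexicographically smallest minimal-mismatch undetected
alignment — deterministic error reports.  A mismatch budget k > ℓ is
clamped to ℓ with a warning ("at most k mismatches" is then vacuous).

## Dominance and Pareto extraction

Dominance is componentwise ≥ on coefficient vectors with one strict
inequality.  The filter is pairwise O(n²·ℓ) with early exit — candidate
sets stay in the low thousands, so no cleverer structure is warranted.
Strictly equivalent seeds (identical vectors) are never dropped: they are
grouped into one equivalence class and all members are reported, because
ties are informative (lossless ties in particular).  Dominance is computed
per alignment length; a joint-over-lengths mode (`compare_joint`) requires
dominance at every length in a range, for users who want candidates robust
across ℓ.

For the continuous models the envelope over the free parameter is obtained
by exact sign analysis: the difference of two candidates is an exact
rational polynomial (Bernoulli in p; for Hit Integration its antiderivative
in the free bound x, for ∫_0^x and ∫_x^1 — the 1/x and 1/(1−x)
normalizations are positive and cannot move a zero, so they are dropped
inside comparisons and applied only to reported values).  Roots in (0, 1)
are isolated with Sturm-based isolating intervals on the rational
polynomial (sympy, domain QQ) after exact deflation of boundary roots, and
refined to brackets of width ≤ 1e−9; the certificate of every breakpoint is
a sign change of the exact polynomial, never a float residual.  Breakpoints
are reported rounded to 5 decimals.  Within each interval the optimum is
the exact argmax at the rational midpoint, which is sound because optima
can change only across a pairwise root; co-optimality means exact
polynomial equality, not numerical closeness.  The zero difference
polynomial is a distinct, signalled condition — an empty root list means
"no crossing", which is a different statement.

For the discrete models the argmax per match count is an exact rational
comparison (for Dirac, an integer comparison, since C(ℓ, m) is shared).
The Heaviside envelope uses windows [m, ℓ].  The lossless border is the
smallest m at which an optimal seed detects every alignment with ≥ m
matches; it is cross-checked against the tropical route at k = ℓ−m.

## Candidate generation

Exhaustive enumeration covers single seeds of moderate weight.  Larger
classes use a seeded hill climb: single-edit moves (swap a `1` with a `0`
inside one member seed, or grow/shrink its span within bounds), with a move
accepted when the new vector dominates the current one, or is incomparable
with a larger Bernoulli value at a pivot probability (default 1/2).  The
pivot guides the walk only; the returned local optima feed the same
parameter-free dominant filter and Pareto extraction, so the final
selection never depends on it.  Defaults: 32 restarts, 1000 steps; the RNG
is a named `random.Random(rng_seed)` recorded in the run manifest, and runs
are reproducible byte-for-byte given the seed.  Returned sets are *locally
dominant* — not dominated by any single-edit neighbour; global dominance is
only guaranteed where the exhaustive route runs.

## Asymptotics

For fixed p ∈ (0, 1) the no-hit probability satisfies
no-hit(ℓ) = β λ^ℓ (1 + o(1)), with λ the Perron root of the hit DFA's
transition matrix restricted to non-final states ('1'-transitions weighted
p, '0'-transitions 1−p).  The DFA is minimized and trimmed first (the
spectral radius is unchanged; conditioning improves).  λ is the spectral
radius — dense eigendecomposition below ~300 states, sparse Arnoldi
(`scipy.sparse.linalg.eigs`, largest magnitude) above.  β is computed by
the ratio method: iterate v ← v(M/λ) from the initial distribution and
report the stabilized total mass, with a successive-ratio stability
certificate (≤ 1e−10 over five consecutive steps); non-convergence raises
rather than returning a stale value.  The ratio route is preferred over
eigenvector normalization formulas because the limit definition is
unambiguous; it is independently cross-checked in the tests against the
exact coefficient-route no-hit probability at ℓ = 80.  Published prefactor
constants for the two weight-11 reference seeds follow a different, not
fully specified normalization and do not coincide with this limit; the
package reports the limit-definition value, whose internal consistency
(β λ^64 reproduces the exact ℓ = 64 no-hit probability to 0.1%) is part of
the test suite.  Default p for reported constants is 0.7.

## Problem sizes and defaults

The test suite and the acceptance script run entirely at desk scale, chosen
to exercise every code path with exhaustible oracles: brute-force
equivalence over all 128 canonical seeds of span ≤ 8 at ℓ = 14 and all 496
two-seed sets of span ≤ 6 at ℓ = 10; dominance and Pareto end-to-end on the
weight-3, span ≤ 6 class at ℓ = 10; crossing points at ℓ = 64 for the two
weight-11 reference seeds; eigenanalysis up to the 1229-state system of a
span-22 seed.  The census-scale experiments (dominant-set sizes over
hundreds of thousands of candidates up to weight 16 and four seeds) are
reachable through the same `run_pipeline` interface but are not part of the
default suite.

## Known limitations

Binary alphabets only: transition-constrained, vector, indel and protein
seeds are out of scope, as are overlap-complexity/covariance heuristics,
multivariate (≥ 2 free parameter) envelopes, and symbolic λ(p).  The
Heaviside/Dirac frequency notation uses the floor convention
m = ⌊ℓ·f⌋.  Hill-climb acceptance is this package's own declared rule, not
a claim of identity with any other implementation.
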