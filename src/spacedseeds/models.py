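"""Sensitivity models computed from the coefficient vector c(pi, m).

Four models share the single object c(pi, m):

* **Bernoulli** — i.i.d. matches with probability ``p``; the hit probability
  is the polynomial ``sum_m c[m] p^m (1-p)^(l-m)``.
* **Hit Integration** — the Bernoulli sensitivity averaged over an interval
  ``[pa, pb]`` of ``p`` (uniform prior on the match probability); computed
  term-wise with a closed-form monomial integral, so the per-(l, pa, pb)
  integrals are independent of the seed.
* **Dirac** — fraction of alignments with *exactly* m matches that are hit.
* **Heaviside** — mean of Dirac over a match-count window [ma, mb].

All values are exact rationals by default (coefficients are integers and
parameters are accepted as rationals); a float is returned only when a float
parameter is passed, in which case it is first lifted to its exact binary
rational so the polynomial evaluation itself stays exact.

Losslessness — does the seed detect *every* alignment with at most k
mismatches? — is decided two independent ways: a tropical (min, +) DP on the
hit DFA, and the tail equality c[m] = C(l, m) for all m >= l - k.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction
from math import comb
from typing import Union

from .automata import build_hit_dfa, minimize
from .counting import CoefficientVector, count_coefficients
from .seedcore import Seed, SeedSet

__all__ = [
    "bernoulli_sensitivity",
    "bernoulli_sensitivity_dp",
    "integrate_monomial",
    "hit_integration",
    "dirac",
    "heaviside",
    "frequency_to_count",
    "frequency_to_counts",
    "lossless_tropical",
    "lossless_from_coefficients",
]

Rational = Union[int, Fraction]


def _rational(p, name: str = "p") -> tuple[Fraction, bool]:
    """Lift a parameter to an exact Fraction; remember if it came in as float."""
    if isinstance(p, float):
        return Fraction(p), True
    return Fraction(p), False


def bernoulli_sensitivity(vec: CoefficientVector, p) -> Fraction | float:
    """Hit probability under a Bernoulli(p) alignment model, degree <= l in p."""
    q, was_float = _rational(p)
    if not 0 <= q <= 1:
        raise ValueError(f"match probability p={p} outside [0, 1]")
    l = vec.length
    one = Fraction(1)
    # Horner-free exact evaluation: powers of q and (1-q)
    acc = Fraction(0)
    for m, c in enumerate(vec.coefficients):
        if c:
            acc += c * q**m * (one - q) ** (l - m)
    return float(acc) if was_float else acc


def bernoulli_sensitivity_dp(seedset: SeedSet | Seed | str, length: int, p) -> Fraction | float:
    """Direct probability-semiring DP on the hit DFA (independent route).

    Transition weights are p on '1' and 1-p on '0'; the mass on the final
    (absorbing) states after ``length`` steps is the hit probability.
    """
    q, was_float = _rational(p)
    if not 0 <= q <= 1:
        raise ValueError(f"match probability p={p} outside [0, 1]")
    dfa = minimize(build_hit_dfa(seedset))
    w0, w1 = 1 - q, q
    mass: dict[int, Fraction] = {dfa.initial: Fraction(1)}
    for _ in range(length):
        new: dict[int, Fraction] = {}
        for st, v in mass.items():
            n0, n1 = dfa.delta[st]
            if w0:
                new[n0] = new.get(n0, Fraction(0)) + v * w0
            if w1:
                new[n1] = new.get(n1, Fraction(0)) + v * w1
        mass = new
    out = sum((mass.get(f, Fraction(0)) for f in dfa.finals), Fraction(0))
    return float(out) if was_float else out


def integrate_monomial(u: int, v: int, pa, pb) -> Fraction:
    """Exact integral of p^u (1-p)^v over [pa, pb] with rational endpoints.

    Uses the binomial expansion of (1-p)^v, giving an antiderivative
    ``sum_k C(v,k) (-1)^k p^(u+k+1) / (u+k+1)`` evaluated at the bounds.
    """
    if u < 0 or v < 0:
        raise ValueError("exponents must be non-negative")
    a, b = Fraction(pa), Fraction(pb)
    if not (0 <= a < b <= 1):
        raise ValueError(f"invalid integration interval [{pa}, {pb}]")

    def antideriv(x: Fraction) -> Fraction:
        acc = Fraction(0)
        xp = x ** (u + 1)
        for k in range(v + 1):
            acc += comb(v, k) * (-1) ** k * xp / (u + k + 1)
            xp *= x
        return acc

    return antideriv(b) - antideriv(a)


def hit_integration(vec: CoefficientVector, pa, pb, normalize: bool = True) -> Fraction:
    """Average Bernoulli sensitivity over p in [pa, pb], exact.

    The monomial integrals depend only on (l, pa, pb), not on the seed, so a
    whole dominant set can share them.
    """
    a, b = Fraction(pa), Fraction(pb)
    if not (0 <= a < b <= 1):
        raise ValueError(f"invalid interval [{pa}, {pb}]")
    l = vec.length
    acc = Fraction(0)
    for m, c in enumerate(vec.coefficients):
        if c:
            acc += c * integrate_monomial(m, l - m, a, b)
    return acc / (b - a) if normalize else acc


def dirac(vec: CoefficientVector, m: int) -> Fraction:
    """Fraction of exactly-m-match alignments of length l that are detected."""
    if not 0 <= m <= vec.length:
        raise ValueError(f"match count m={m} outside [0, {vec.length}]")
    return Fraction(vec.coefficients[m], comb(vec.length, m))


def heaviside(vec: CoefficientVector, ma: int, mb: int) -> Fraction:
    """Mean Dirac sensitivity over match counts ma..mb (inclusive).

    The degenerate window ma == mb is allowed and equals Dirac at m.
    """
    if not 0 <= ma <= mb <= vec.length:
        raise ValueError(f"invalid match-count window [{ma}, {mb}] for l={vec.length}")
    total = sum(dirac(vec, m) for m in range(ma, mb + 1))
    return total / (mb - ma + 1)


def frequency_to_count(f, length: int) -> int:
    """Match frequency -> match count, floor convention: m = floor(l * f)."""
    fr = Fraction(f)
    if not 0 <= fr <= 1:
        raise ValueError(f"frequency {f} outside [0, 1]")
    return math.floor(length * fr)


def frequency_to_counts(fa, fb, length: int) -> tuple[int, int]:
    """(fa, fb) -> (ma, mb) for the frequency-notation Heaviside."""
    if not Fraction(fa) < Fraction(fb):
        raise ValueError("need fa < fb")
    return frequency_to_count(fa, length), frequency_to_count(fb, length)


def lossless_tropical(
    seedset: SeedSet | Seed | str, length: int, k: int
) -> tuple[bool, str | None]:
    """(l, k)-losslessness via the tropical (min, +) DP on the hit DFA.

    A '0'-transition costs one mismatch, a '1'-transition is free.  The seed
    set is lossless iff every non-final state, after l steps, has minimal
    cost strictly greater than k.  On failure, the lexicographically smallest
    minimal-mismatch undetected alignment is returned as a witness.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    if k < 0:
        raise ValueError("mismatch budget k must be >= 0")
    if k > length:
        warnings.warn(f"k={k} exceeds l={length}; clamped to {length}", stacklevel=2)
        k = length
    dfa = minimize(build_hit_dfa(seedset))
    INF = float("inf")
    n = dfa.n_states
    # backward DP: B[i][q] = min mismatches on a length-(l-i) suffix from q
    # that ends in a NON-final state
    B = [0.0 if q not in dfa.finals else INF for q in range(n)]
    layers = [B]
    for _ in range(length):
        prev = layers[0]
        cur = [INF] * n
        for q in range(n):
            n0, n1 = dfa.delta[q]
            best = prev[n1]          # '1' costs 0
            c0 = prev[n0] + 1        # '0' costs 1
            if c0 < best:
                best = c0
            cur[q] = best
        layers.insert(0, cur)
    min_cost = layers[0][dfa.initial]
    if min_cost > k:
        return True, None
    # witness: greedy lexicographically smallest ('0' < '1') minimal-cost path
    witness = []
    q = dfa.initial
    for i in range(length):
        target = layers[i][q]
        n0, n1 = dfa.delta[q]
        if layers[i + 1][n0] + 1 == target:
            witness.append("0")
            q = n0
        else:
            witness.append("1")
            q = n1
    return False, "".join(witness)


def lossless_from_coefficients(vec: CoefficientVector, k: int) -> bool:
    """(l, k)-losslessness via the tail equality c[m] = C(l, m) for m >= l-k."""
    if k < 0:
        raise ValueError("mismatch budget k must be >= 0")
    l = vec.length
    if k > l:
        warnings.warn(f"k={k} exceeds l={l}; clamped to {l}", stacklevel=2)
        k = l
    return all(vec.coefficients[m] == comb(l, m) for m in range(l - k, l + 1))
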