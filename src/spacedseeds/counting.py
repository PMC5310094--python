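"""Counting-semiring dynamic programming: the coefficient vector c(pi, m).

``c[m]`` is the number of binary alignments of length ``l`` with exactly
``m`` match symbols that are detected (hit at least once) by a seed set.
The DP runs over the hit DFA keeping, per state, one exact integer count per
match count — equivalent to counting paths in the lazy intersection product
of the hit DFA with the linear 1-counting automaton.  Counts are unbounded
Python integers, so no overflow can occur even at l=64 with multiple seeds.

A 2**l brute-force oracle (bit-parallel window tests) is provided for
cross-validation at small lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

from .automata import HitAutomaton, build_hit_dfa, minimize
from .seedcore import Seed, SeedSet

__all__ = [
    "CoefficientVector",
    "CoefficientDP",
    "count_coefficients",
    "count_coefficients_bruteforce",
    "state_occupancy_totals",
]

BRUTEFORCE_CAP = 16


def _as_seedset(seedset: SeedSet | Seed | str) -> SeedSet:
    if isinstance(seedset, str):
        return SeedSet.of(*seedset.split(","))
    if isinstance(seedset, Seed):
        return SeedSet((seedset,))
    return seedset


@dataclass(frozen=True)
class CoefficientVector:
    """c[m] for m = 0..length, with provenance."""

    length: int
    coefficients: tuple[int, ...]
    seedset: SeedSet | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.length + 1:
            raise ValueError("coefficient vector must have length l+1")
        if any(c < 0 for c in self.coefficients):
            raise ValueError("coefficients must be non-negative")

    def __getitem__(self, m: int) -> int:
        return self.coefficients[m]

    def __len__(self) -> int:
        return self.length + 1

    @property
    def total_accepted(self) -> int:
        """Total number of length-l strings accepted by the hit DFA."""
        return sum(self.coefficients)

    def ratio(self, m: int) -> Fraction:
        """c[m] / C(l, m) — the Dirac sensitivity at m, exact."""
        return Fraction(self.coefficients[m], comb(self.length, m))

    def to_tsv(self) -> str:
        """Machine-readable coefficient table: m, c_m, binom(l,m), exact ratio."""
        rows = ["m\tc_m\tbinom_l_m\tratio"]
        for m, c in enumerate(self.coefficients):
            b = comb(self.length, m)
            r = Fraction(c, b)
            rows.append(f"{m}\t{c}\t{b}\t{r.numerator}/{r.denominator}")
        return "\n".join(rows) + "\n"


class CoefficientDP:
    """Incremental counting DP over a hit DFA.

    Holds, for every DFA state, the list of counts indexed by match count.
    ``advance_to(l)`` extends the recursion; snapshots at increasing lengths
    are identical to fresh from-scratch runs.
    """

    def __init__(self, seedset: SeedSet | Seed | str, minimize_dfa: bool = True):
        self.seedset = _as_seedset(seedset)
        dfa = build_hit_dfa(self.seedset)
        self.dfa: HitAutomaton = minimize(dfa) if minimize_dfa else dfa
        self.length = 0
        # counts[q][m] = number of length-`length` strings with m matches ending in q
        self.counts: dict[int, list[int]] = {self.dfa.initial: [1]}

    def advance_to(self, length: int) -> None:
        if length < self.length:
            raise ValueError("cannot rewind the DP; build a fresh one")
        delta = self.dfa.delta
        for _ in range(length - self.length):
            new: dict[int, list[int]] = {}
            for q, vec in self.counts.items():
                n0, n1 = delta[q]
                t0 = new.get(n0)
                if t0 is None:
                    t0 = new[n0] = [0] * (len(vec))
                elif len(t0) < len(vec):
                    t0.extend([0] * (len(vec) - len(t0)))
                for m, c in enumerate(vec):
                    if c:
                        t0[m] += c
                t1 = new.get(n1)
                need = len(vec) + 1
                if t1 is None:
                    t1 = new[n1] = [0] * need
                elif len(t1) < need:
                    t1.extend([0] * (need - len(t1)))
                for m, c in enumerate(vec):
                    if c:
                        t1[m + 1] += c
            self.counts = new
            self.length += 1

    def coefficients(self) -> CoefficientVector:
        l = self.length
        out = [0] * (l + 1)
        for q in self.dfa.finals:
            vec = self.counts.get(q)
            if vec:
                for m, c in enumerate(vec):
                    out[m] += c
        return CoefficientVector(l, tuple(out), self.seedset)

    def occupancy(self) -> dict[int, list[int]]:
        """Per-state counts at the current length (final and non-final)."""
        return {q: list(v) for q, v in self.counts.items()}


def count_coefficients(
    seedset: SeedSet | Seed | str, length: int, minimize_dfa: bool = True
) -> CoefficientVector:
    """Exact c[m] for m = 0..length via the counting-semiring DP."""
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    dp = CoefficientDP(seedset, minimize_dfa=minimize_dfa)
    dp.advance_to(length)
    return dp.coefficients()


def state_occupancy_totals(seedset: SeedSet | Seed | str, length: int) -> list[list[int]]:
    """Per-step totals over all DFA states, indexed [i][m].

    Conservation law: the total over states at step i with m matches must be
    C(i, m) — every binary string of length i ends in exactly one state.
    """
    dp = CoefficientDP(seedset)
    totals: list[list[int]] = []
    for i in range(length + 1):
        dp.advance_to(i)
        row = [0] * (i + 1)
        for vec in dp.counts.values():
            for m, c in enumerate(vec):
                row[m] += c
        totals.append(row)
    return totals


def count_coefficients_bruteforce(
    seedset: SeedSet | Seed | str, length: int, cap: int = BRUTEFORCE_CAP
) -> CoefficientVector:
    """Oracle: enumerate all 2**l strings and classify by (m, hit?).

    Independent of the DFA route — hit testing is done by direct window
    comparison on the integer encoding of each string.
    """
    seedset = _as_seedset(seedset)
    if length > cap:
        raise ValueError(f"brute force capped at l={cap} (asked {length})")
    masks = []
    for seed in seedset:
        sm = 0
        for j, ch in enumerate(seed.pattern):
            if ch == "1":
                sm |= 1 << j
        masks.append((sm, seed.span))
    out = [0] * (length + 1)
    for x in range(1 << length):
        hit = False
        for sm, span in masks:
            for off in range(length - span + 1):
                if (x >> off) & sm == sm:
                    hit = True
                    break
            if hit:
                break
        if hit:
            out[x.bit_count()] += 1
    return CoefficientVector(length, tuple(out), seedset)
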