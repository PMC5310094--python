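"""Parameter-free optimal-seed extraction (the Pareto envelope).

Stage two of the two-stage procedure: given the dominant candidates, decide
*for every value of the free model parameter* which candidate is best,
without ever fixing that parameter.

For the continuous models (Bernoulli in ``p``; Hit Integration with a free
integration bound ``x`` for the intervals [0, x] or [x, 1]) optimality
changes only where the exact difference polynomial of two candidates crosses
zero, so the parameter domain (0, 1) is partitioned by the isolated real
roots of all pairwise differences.  Root isolation is exact-arithmetic-first
(Sturm-based isolating intervals on the rational polynomial) refined by
bisection to a requested width; the certificate of each breakpoint is a sign
change of the exact polynomial, never a float residual.

For the discrete models (Dirac at each match count m; Heaviside over
[m, l]) optimality is an exact rational argmax per parameter value, and the
*lossless border* — the smallest m from which an optimal seed detects every
alignment with >= m matches — is annotated.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import sympy

from .counting import CoefficientVector
from .models import dirac as dirac_value
from .seedcore import SeedSet

__all__ = [
    "ZeroPolynomialError",
    "SensitivityPolynomial",
    "bernoulli_polynomial",
    "difference_polynomial",
    "Root",
    "isolate_roots",
    "Segment",
    "ContinuousParetoResult",
    "DiscreteParetoResult",
    "pareto_continuous",
    "pareto_discrete",
]

CONTINUOUS_MODELS = ("bernoulli", "hi_0x", "hi_x1")
DISCRETE_MODELS = ("dirac", "heaviside_x1")


class ZeroPolynomialError(ValueError):
    """Root isolation was asked for the identically-zero polynomial."""


@dataclass(frozen=True)
class SensitivityPolynomial:
    """Exact rational polynomial in the power basis.

    ``coeffs[j]`` multiplies ``var**j``.  Used both for sensitivities (values
    on [0,1] lie in [0,1]) and for their differences (values in [-1,1]).
    """

    coeffs: tuple[Fraction, ...]
    var: str = "p"

    @property
    def degree(self) -> int:
        d = len(self.coeffs) - 1
        while d > 0 and self.coeffs[d] == 0:
            d -= 1
        return d

    @property
    def is_zero(self) -> bool:
        return all(c == 0 for c in self.coeffs)

    def __call__(self, x) -> Fraction | float:
        as_float = isinstance(x, float)
        xf = Fraction(x)
        acc = Fraction(0)
        for c in reversed(self.coeffs):
            acc = acc * xf + c
        return float(acc) if as_float else acc

    def __sub__(self, other: "SensitivityPolynomial") -> "SensitivityPolynomial":
        n = max(len(self.coeffs), len(other.coeffs))
        a = list(self.coeffs) + [Fraction(0)] * (n - len(self.coeffs))
        b = list(other.coeffs) + [Fraction(0)] * (n - len(other.coeffs))
        return SensitivityPolynomial(tuple(x - y for x, y in zip(a, b)), self.var)

    def derivative(self) -> "SensitivityPolynomial":
        return SensitivityPolynomial(
            tuple(j * c for j, c in enumerate(self.coeffs))[1:] or (Fraction(0),), self.var
        )

    def antiderivative(self) -> "SensitivityPolynomial":
        """Integral from 0 (zero constant term)."""
        return SensitivityPolynomial(
            (Fraction(0),) + tuple(c / (j + 1) for j, c in enumerate(self.coeffs)), self.var
        )

    def to_sympy(self, symbol: sympy.Symbol | None = None) -> sympy.Poly:
        x = symbol if symbol is not None else sympy.Symbol(self.var)
        expr = sum(
            sympy.Rational(c.numerator, c.denominator) * x**j
            for j, c in enumerate(self.coeffs)
            if c != 0
        )
        return sympy.Poly(expr if expr != 0 else sympy.Integer(0), x, domain="QQ")


def bernoulli_polynomial(vec: CoefficientVector) -> SensitivityPolynomial:
    """Expand sum_m c[m] p^m (1-p)^(l-m) into the power basis, exactly."""
    l = vec.length
    out = [0] * (l + 1)
    for m, c in enumerate(vec.coefficients):
        if c:
            for j in range(m, l + 1):
                out[j] += c * comb(l - m, j - m) * (-1) ** (j - m)
    return SensitivityPolynomial(tuple(Fraction(v) for v in out), "p")


def difference_polynomial(
    vec_a: CoefficientVector, vec_b: CoefficientVector, model: str = "bernoulli"
) -> SensitivityPolynomial:
    """Exact polynomial whose sign decides which of two seeds is better.

    * ``bernoulli`` — Pr_a(p) - Pr_b(p), variable p.
    * ``hi_0x``     — integral over [0, x] of the Bernoulli difference,
      variable x (the 1/x normalization is positive, hence sign-irrelevant).
    * ``hi_x1``     — integral over [x, 1] of the Bernoulli difference.
    """
    if vec_a.length != vec_b.length:
        raise ValueError("length mismatch between coefficient vectors")
    if model not in CONTINUOUS_MODELS:
        raise ValueError(f"unknown continuous model {model!r}")
    diff = bernoulli_polynomial(vec_a) - bernoulli_polynomial(vec_b)
    if model == "bernoulli":
        return diff
    anti = diff.antiderivative()
    if model == "hi_0x":
        return SensitivityPolynomial(anti.coeffs, "x")
    # hi_x1: F(1) - F(x)
    total = anti(Fraction(1))
    coeffs = tuple(-c for c in anti.coeffs)
    return SensitivityPolynomial((coeffs[0] + total,) + coeffs[1:], "x")


@dataclass(frozen=True)
class Root:
    """An isolated real root, bracketed by exact rationals."""

    lo: Fraction
    hi: Fraction
    multiplicity: int = 1

    @property
    def value(self) -> float:
        return float((self.lo + self.hi) / 2)

    def rounded(self, ndigits: int = 5) -> float:
        return round(self.value, ndigits)


def isolate_roots(
    poly: SensitivityPolynomial, tol: float = 1e-9, lo: Fraction = Fraction(0), hi: Fraction = Fraction(1)
) -> list[Root]:
    """All real roots in the *open* interval (lo, hi), bracketed to <= tol.

    Isolation uses Sturm-based exact isolating intervals on the rational
    polynomial; each bracket is then refined until its width is below tol.
    Boundary roots (at lo or hi) are excluded.  Raises
    :class:`ZeroPolynomialError` on the zero polynomial — an empty root list
    means "no roots", which is a different statement.
    """
    if poly.is_zero:
        raise ZeroPolynomialError("cannot isolate roots of the zero polynomial")
    if tol <= 0:
        raise ValueError("tol must be positive")
    # deflate roots sitting exactly on the boundaries so the isolation below
    # can only ever report interior roots
    coeffs = list(poly.coeffs)
    while len(coeffs) > 1 and poly_eval(coeffs, lo) == 0:
        coeffs = _deflate(coeffs, lo)
    while len(coeffs) > 1 and poly_eval(coeffs, hi) == 0:
        coeffs = _deflate(coeffs, hi)
    work = SensitivityPolynomial(tuple(coeffs), poly.var)
    if work.is_zero:
        raise ZeroPolynomialError("cannot isolate roots of the zero polynomial")
    sp = work.to_sympy()
    eps = sympy.Rational(Fraction(tol).limit_denominator(10**15))
    intervals = sp.intervals(inf=sympy.Rational(lo), sup=sympy.Rational(hi), eps=eps, sqf=False)
    out: list[Root] = []
    for (a, b), mult in intervals:
        fa, fb = Fraction(int(a.p), int(a.q)), Fraction(int(b.p), int(b.q))
        if fa == fb and (fa <= lo or fa >= hi):
            continue
        out.append(Root(fa, fb, mult))
    out.sort(key=lambda r: (r.lo, r.hi))
    return out


def poly_eval(coeffs: Sequence[Fraction], x: Fraction) -> Fraction:
    acc = Fraction(0)
    for c in reversed(coeffs):
        acc = acc * x + c
    return acc


def _deflate(coeffs: list[Fraction], root: Fraction) -> list[Fraction]:
    """Exact synthetic division by (x - root); assumes root is a root."""
    n = len(coeffs) - 1
    out = [Fraction(0)] * n
    out[n - 1] = coeffs[n]
    for j in range(n - 1, 0, -1):
        out[j - 1] = coeffs[j] + root * out[j]
    return out


@dataclass(frozen=True)
class Segment:
    """One maximal interval of the parameter domain with a constant optimum."""

    lo: float
    hi: float
    optimal: tuple[SeedSet, ...]
    value_at_midpoint: float


@dataclass(frozen=True)
class ContinuousParetoResult:
    model: str
    length: int
    breakpoints: tuple[float, ...]
    segments: tuple[Segment, ...]

    def optimal_at(self, x: float) -> tuple[SeedSet, ...]:
        for seg in self.segments:
            if seg.lo <= x <= seg.hi:
                return seg.optimal
        raise ValueError(f"{x} outside the parameter domain")

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "l": self.length,
            "breakpoints": list(self.breakpoints),
            "segments": [
                {
                    "lo": s.lo,
                    "hi": s.hi,
                    "optimal": [str(ss) for ss in s.optimal],
                    "value_at_midpoint": s.value_at_midpoint,
                }
                for s in self.segments
            ],
        }


@dataclass(frozen=True)
class DiscreteParetoResult:
    model: str
    length: int
    optimal_by_m: tuple[tuple[SeedSet, ...], ...]  # index = m (Dirac) or ma (Heaviside [m, l])
    values_by_m: tuple[Fraction, ...]
    lossless_border: int | None  # smallest m at which an optimal seed is lossless

    @property
    def lossless_fraction(self) -> Fraction | None:
        if self.lossless_border is None:
            return None
        return Fraction(self.lossless_border, self.length)

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "l": self.length,
            "optimal_by_m": [[str(ss) for ss in opt] for opt in self.optimal_by_m],
            "values_by_m": [f"{v.numerator}/{v.denominator}" for v in self.values_by_m],
            "lossless_border": self.lossless_border,
            "lossless_fraction": (
                None
                if self.lossless_border is None
                else f"{self.lossless_border}/{self.length}"
            ),
        }


def _candidate_polys(
    candidates: Sequence[tuple[SeedSet, CoefficientVector]], model: str
) -> list[SensitivityPolynomial]:
    polys = []
    for _, vec in candidates:
        base = bernoulli_polynomial(vec)
        if model == "bernoulli":
            polys.append(base)
        elif model == "hi_0x":
            polys.append(SensitivityPolynomial(base.antiderivative().coeffs, "x"))
        elif model == "hi_x1":
            anti = base.antiderivative()
            total = anti(Fraction(1))
            coeffs = tuple(-c for c in anti.coeffs)
            polys.append(SensitivityPolynomial((coeffs[0] + total,) + coeffs[1:], "x"))
        else:
            raise ValueError(f"unknown continuous model {model!r}")
    return polys


def pareto_continuous(
    candidates: Sequence[tuple[SeedSet, CoefficientVector]],
    model: str = "bernoulli",
    tol: float = 1e-9,
) -> ContinuousParetoResult:
    """Partition (0, 1) into intervals of constant optimal seed set.

    Co-optimality within an interval means *exact* polynomial equality; the
    per-interval argmax is taken at the exact rational midpoint, which is
    sound because optima can change only across a pairwise difference root.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    lengths = {vec.length for _, vec in candidates}
    if len(lengths) != 1:
        raise ValueError("mixed alignment lengths")
    length = lengths.pop()
    polys = _candidate_polys(candidates, model)

    breakpts: set[Fraction] = set()
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            diff = polys[i] - polys[j]
            if diff.is_zero:
                continue
            for r in isolate_roots(diff, tol=tol):
                breakpts.add((r.lo + r.hi) / 2)
    cuts = [Fraction(0)] + sorted(breakpts) + [Fraction(1)]

    segments: list[Segment] = []
    prev_opt: tuple[int, ...] | None = None
    for lo, hi in zip(cuts, cuts[1:]):
        mid = (lo + hi) / 2
        vals = [poly(mid) for poly in polys]
        best = max(vals)
        opt_idx = tuple(i for i, v in enumerate(vals) if v == best)
        if prev_opt is not None and opt_idx == prev_opt:
            last = segments.pop()
            segments.append(
                Segment(last.lo, float(hi), last.optimal, last.value_at_midpoint)
            )
        else:
            # normalization by interval width for HI models (positive, sign-irrelevant
            # for the argmax, applied to the reported value)
            value = best
            if model == "hi_0x" and mid != 0:
                value = best / mid
            elif model == "hi_x1" and mid != 1:
                value = best / (1 - mid)
            segments.append(
                Segment(
                    float(lo),
                    float(hi),
                    tuple(candidates[i][0] for i in opt_idx),
                    float(value),
                )
            )
        prev_opt = opt_idx
    kept_breaks = tuple(s.lo for s in segments[1:])
    return ContinuousParetoResult(model, length, kept_breaks, tuple(segments))


def pareto_discrete(
    candidates: Sequence[tuple[SeedSet, CoefficientVector]],
    model: str = "dirac",
) -> DiscreteParetoResult:
    """Exact argmax per match count; Heaviside uses the window [m, l].

    The lossless border is the smallest m at which some optimal seed attains
    c[m'] = C(l, m') for every m' >= m (it then detects *all* alignments
    with at least m matches).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    lengths = {vec.length for _, vec in candidates}
    if len(lengths) != 1:
        raise ValueError("mixed alignment lengths")
    length = lengths.pop()
    if model not in DISCRETE_MODELS:
        raise ValueError(f"unknown discrete model {model!r}")

    def score(vec: CoefficientVector, m: int) -> Fraction:
        if model == "dirac":
            return dirac_value(vec, m)
        # heaviside over [m, l]; the 1/(l-m+1) normalization is shared
        return sum(
            (dirac_value(vec, mm) for mm in range(m, length + 1)), Fraction(0)
        ) / (length - m + 1)

    def lossless_from(vec: CoefficientVector, m: int) -> bool:
        return all(vec.coefficients[mm] == comb(length, mm) for mm in range(m, length + 1))

    optimal_by_m: list[tuple[SeedSet, ...]] = []
    values_by_m: list[Fraction] = []
    border: int | None = None
    for m in range(length + 1):
        vals = [score(vec, m) for _, vec in candidates]
        best = max(vals)
        opt = tuple(i for i, v in enumerate(vals) if v == best)
        optimal_by_m.append(tuple(candidates[i][0] for i in opt))
        values_by_m.append(best)
        if border is None and any(lossless_from(candidates[i][1], m) for i in opt):
            border = m
    return DiscreteParetoResult(model, length, tuple(optimal_by_m), tuple(values_by_m), border)
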