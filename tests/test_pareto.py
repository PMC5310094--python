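"""Difference polynomials, exact root isolation, and Pareto extraction."""

from fractions import Fraction

import pytest

from spacedseeds import (
    SeedSet,
    bernoulli_polynomial,
    bernoulli_sensitivity,
    count_coefficients,
    difference_polynomial,
    dirac,
    dominant_filter,
    isolate_roots,
    lossless_tropical,
    pareto_continuous,
    pareto_discrete,
)
from spacedseeds.design import enumerate_seeds
from spacedseeds.models import heaviside
from spacedseeds.pareto import SensitivityPolynomial, ZeroPolynomialError


def test_polynomial_expansion_matches_model_evaluation():
    vec = count_coefficients("1101", 7)
    poly = bernoulli_polynomial(vec)
    for i in range(0, 11):
        p = Fraction(i, 10)
        assert poly(p) == bernoulli_sensitivity(vec, p)


def test_difference_of_identical_vectors_is_zero():
    vec = count_coefficients("101", 6)
    assert difference_polynomial(vec, vec, "bernoulli").is_zero
    with pytest.raises(ZeroPolynomialError):
        isolate_roots(difference_polynomial(vec, vec, "bernoulli"))


def test_hi_difference_derivative_is_bernoulli_difference():
    """d/dx of the integral-from-0-to-x difference recovers the integrand."""
    va = count_coefficients("1101", 8)
    vb = count_coefficients("1011", 8)
    bern = difference_polynomial(va, vb, "bernoulli")
    hi = difference_polynomial(va, vb, "hi_0x")
    assert hi.derivative().coeffs == bern.coeffs
    # and hi_0x + hi_x1 is the constant total integral
    hi_rev = difference_polynomial(va, vb, "hi_x1")
    total = SensitivityPolynomial(
        tuple(a + b for a, b in zip(hi.coeffs, hi_rev.coeffs)), "x"
    )
    assert total.degree == 0


def test_isolate_roots_known_polynomials():
    # p(1-p): both roots on the boundary, none inside
    p = SensitivityPolynomial((Fraction(0), Fraction(1), Fraction(-1)))
    assert isolate_roots(p) == []
    # (x - 1/3)(x - 2/3)
    q = SensitivityPolynomial((Fraction(2, 9), Fraction(-1), Fraction(1)))
    roots = isolate_roots(q, tol=1e-10)
    assert len(roots) == 2
    assert roots[0].lo <= Fraction(1, 3) <= roots[0].hi
    assert roots[1].lo <= Fraction(2, 3) <= roots[1].hi
    # (x - 1/2)^2: double root
    r = SensitivityPolynomial((Fraction(1, 4), Fraction(-1), Fraction(1)))
    (root,) = isolate_roots(r)
    assert root.multiplicity == 2
    assert root.lo <= Fraction(1, 2) <= root.hi


def test_root_brackets_certified_by_sign_change():
    va = count_coefficients("1101", 10)
    vb = count_coefficients("10101", 10)
    diff = difference_polynomial(va, vb, "bernoulli")
    for root in isolate_roots(diff):
        if root.lo != root.hi:
            assert (diff(root.lo) > 0) != (diff(root.hi) > 0)
            assert float(root.hi - root.lo) <= 1e-9


def _dominant_reps(weight, max_span, l):
    cands = [
        (SeedSet.of(s.pattern), count_coefficients(s, l))
        for s in enumerate_seeds(weight, max_span)
        if s.span <= l
    ]
    return [(c.representative, c.vector) for c in dominant_filter(cands)]


def test_single_candidate_envelope_is_whole_domain():
    reps = _dominant_reps(2, 2, 6)  # only the seed 11
    res = pareto_continuous(reps, "bernoulli")
    assert len(res.segments) == 1
    assert (res.segments[0].lo, res.segments[0].hi) == (0.0, 1.0)


@pytest.mark.parametrize("model", ["bernoulli", "hi_0x", "hi_x1"])
def test_envelope_matches_pointwise_max(model):
    reps = _dominant_reps(3, 6, 10)
    res = pareto_continuous(reps, model)
    by_pattern = {str(ss): vec for ss, vec in reps}
    from spacedseeds.models import hit_integration

    for i in range(1, 50):
        x = Fraction(i, 50)
        if any(abs(x - Fraction(b).limit_denominator(10**12)) < Fraction(1, 10**6) for b in res.breakpoints):
            continue

        def value(vec):
            if model == "bernoulli":
                return bernoulli_sensitivity(vec, x)
            if model == "hi_0x":
                return hit_integration(vec, 0, x)
            return hit_integration(vec, x, 1)

        best = max(value(v) for v in by_pattern.values())
        opt = res.optimal_at(float(x))
        assert any(value(by_pattern[str(ss)]) == best for ss in opt)


def test_envelope_optima_are_dominant_and_segments_partition():
    reps = _dominant_reps(3, 6, 10)
    dominant_patterns = {str(ss) for ss, _ in reps}
    res = pareto_continuous(reps, "bernoulli")
    assert res.segments[0].lo == 0.0 and res.segments[-1].hi == 1.0
    for a, b in zip(res.segments, res.segments[1:]):
        assert a.hi == b.lo
        assert set(map(str, a.optimal)) != set(map(str, b.optimal))
    for seg in res.segments:
        for ss in seg.optimal:
            assert str(ss) in dominant_patterns


def test_discrete_all_coopt_at_full_match():
    reps = _dominant_reps(3, 6, 10)
    res = pareto_discrete(reps, "dirac")
    assert set(map(str, res.optimal_by_m[10])) == {str(ss) for ss, _ in reps}
    assert res.values_by_m[10] == 1


@pytest.mark.parametrize("model", ["dirac", "heaviside_x1"])
def test_discrete_argmax_matches_bruteforce(model):
    reps = _dominant_reps(3, 6, 10)
    res = pareto_discrete(reps, model)
    for m in range(11):
        def score(vec):
            if model == "dirac":
                return dirac(vec, m)
            return heaviside(vec, m, 10)

        best = max(score(v) for _, v in reps)
        assert res.values_by_m[m] == best
        assert {str(ss) for ss in res.optimal_by_m[m]} == {
            str(ss) for ss, v in reps if score(v) == best
        }


def test_lossless_border_agrees_with_tropical_dp():
    reps = _dominant_reps(3, 6, 10)
    res = pareto_discrete(reps, "dirac")
    m = res.lossless_border
    assert m is not None
    l = res.length
    hit = False
    for ss in res.optimal_by_m[m]:
        ok, _ = lossless_tropical(ss, l, l - m)
        hit = hit or ok
    assert hit
    # below the border no optimal seed is lossless
    if m > 0:
        for ss in res.optimal_by_m[m - 1]:
            ok, _ = lossless_tropical(ss, l, l - (m - 1))
            assert not ok
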