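"""Dominance partial order, the dominant filter, and its model soundness."""

import random
from fractions import Fraction

import pytest

from spacedseeds import (
    CoefficientVector,
    DominanceVerdict,
    SeedSet,
    bernoulli_sensitivity,
    compare,
    count_coefficients,
    dirac,
    dominant_filter,
    heaviside,
    hit_integration,
)
from spacedseeds.design import enumerate_seeds


def vec(coeffs):
    return CoefficientVector(len(coeffs) - 1, tuple(coeffs))


def test_compare_basic_verdicts():
    assert compare(vec([0, 1, 2]), vec([0, 1, 2])) is DominanceVerdict.EQUIVALENT
    assert compare(vec([0, 1, 2]), vec([0, 1, 1])) is DominanceVerdict.A_DOMINATES_B
    assert compare(vec([0, 1, 1]), vec([0, 1, 2])) is DominanceVerdict.B_DOMINATES_A
    assert compare(vec([0, 2, 1]), vec([0, 1, 2])) is DominanceVerdict.INCOMPARABLE
    with pytest.raises(ValueError):
        compare(vec([0, 1]), vec([0, 1, 2]))


def test_weight11_pair_incomparable_at_64(ph1_vec64, contig11_vec64):
    """Contiguous 11111111111 and Patternhunter I cross over: the contiguous
    seed detects more low-match alignments, the spaced seed more high-match
    ones — so dominance cannot separate them."""
    assert compare(contig11_vec64, ph1_vec64) is DominanceVerdict.INCOMPARABLE
    c, a = contig11_vec64.coefficients, ph1_vec64.coefficients
    for m in range(65):
        if m < 11:
            assert c[m] == a[m] == 0  # below the common weight
        elif m <= 18:
            assert c[m] > a[m]
        else:
            assert c[m] <= a[m]
            if m <= 59:
                assert c[m] < a[m]


def _candidates(weight, max_span, l):
    return [
        (SeedSet.of(s.pattern), count_coefficients(s, l))
        for s in enumerate_seeds(weight, max_span)
        if s.span <= l
    ]


def test_dominant_filter_equals_pairwise_oracle():
    cands = _candidates(3, 6, 10)
    classes = dominant_filter(cands)
    kept = {str(m) for c in classes for m in c.members}
    # naive definition check: dominated iff some other candidate is >= with a strict >
    expected = set()
    for ss, v in cands:
        dominated = False
        for ss2, v2 in cands:
            if v2.coefficients == v.coefficients:
                continue
            if all(a >= b for a, b in zip(v2.coefficients, v.coefficients)):
                dominated = True
                break
        if not dominated:
            expected.add(str(ss))
    assert kept == expected


def test_filter_output_is_an_antichain_and_order_independent():
    cands = _candidates(3, 6, 10)
    classes = dominant_filter(cands)
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            if i != j:
                assert compare(ci.vector, cj.vector) is DominanceVerdict.INCOMPARABLE
    shuffled = cands[:]
    random.Random(7).shuffle(shuffled)
    again = {str(m) for c in dominant_filter(shuffled) for m in c.members}
    assert again == {str(m) for c in classes for m in c.members}


def test_equivalent_vectors_grouped_not_dropped():
    a = (SeedSet.of("11"), vec([0, 0, 2, 1]))
    b = (SeedSet.of("101"), vec([0, 0, 2, 1]))  # forced-equal vector for the test
    classes = dominant_filter([a, b])
    assert len(classes) == 1
    assert {str(m) for m in classes[0].members} == {"11", "101"}


def test_dominance_soundness_across_all_models():
    """If A dominates B, A is at least as sensitive under every model and
    every parameter — the reason the filter is model-free."""
    cands = _candidates(3, 5, 9)
    pairs = [
        (va, vb)
        for _, va in cands
        for _, vb in cands
        if compare(va, vb) is DominanceVerdict.A_DOMINATES_B
    ]
    assert pairs, "expected at least one strictly dominating pair"
    grid = [Fraction(i, 10) for i in range(11)]
    for va, vb in pairs[:10]:
        for p in grid:
            assert bernoulli_sensitivity(va, p) >= bernoulli_sensitivity(vb, p)
        for a, b in [(0, 1), (Fraction(1, 2), 1), (Fraction(1, 5), Fraction(2, 5))]:
            assert hit_integration(va, a, b) >= hit_integration(vb, a, b)
        for m in range(10):
            assert dirac(va, m) >= dirac(vb, m)
        for ma in range(10):
            assert heaviside(va, ma, 9) >= heaviside(vb, ma, 9)


def test_model_optima_always_dominant():
    """Whatever model and parameter, the best candidate survives the filter."""
    cands = _candidates(3, 6, 10)
    kept = {str(ss) for c in dominant_filter(cands) for ss in c.members}
    for p in [Fraction(i, 8) for i in range(9)]:
        best = max(cands, key=lambda c: bernoulli_sensitivity(c[1], p))
        assert str(best[0]) in kept
    for m in range(11):
        best = max(cands, key=lambda c: dirac(c[1], m))
        assert str(best[0]) in kept
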