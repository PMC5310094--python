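"""The four sensitivity models, exact arithmetic, and dual-route losslessness."""

from fractions import Fraction
from math import comb

import pytest
from scipy.integrate import quad

from spacedseeds import (
    SeedSet,
    bernoulli_sensitivity,
    bernoulli_sensitivity_dp,
    count_coefficients,
    dirac,
    frequency_to_count,
    frequency_to_counts,
    heaviside,
    hit_integration,
    integrate_monomial,
    lossless_from_coefficients,
    lossless_tropical,
)

P07 = Fraction(7, 10)


class TestBernoulli:
    def test_worked_values_are_exact(self):
        v4 = count_coefficients("1101", 4)
        v5 = count_coefficients("1101", 5)
        assert bernoulli_sensitivity(v4, P07) == Fraction(343, 1000)
        assert bernoulli_sensitivity(v5, P07) == Fraction(51793, 100000)

    @pytest.mark.parametrize("pattern", ["1101", "101", "10011"])
    @pytest.mark.parametrize("l", [5, 8, 11])
    def test_two_route_consistency(self, pattern, l):
        """Coefficient evaluation equals the direct probability-semiring DP."""
        vec = count_coefficients(pattern, l)
        for p in (Fraction(1, 3), Fraction(7, 10), Fraction(9, 10)):
            assert bernoulli_sensitivity(vec, p) == bernoulli_sensitivity_dp(pattern, l, p)

    def test_boundary_probabilities(self):
        vec = count_coefficients("1101", 6)
        assert bernoulli_sensitivity(vec, 1) == 1
        assert bernoulli_sensitivity(vec, 0) == 0
        with pytest.raises(ValueError):
            bernoulli_sensitivity(vec, Fraction(3, 2))

    def test_monotone_in_p_and_in_length(self):
        vec = count_coefficients("1101", 8)
        grid = [Fraction(i, 20) for i in range(21)]
        vals = [bernoulli_sensitivity(vec, p) for p in grid]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        longer = count_coefficients("1101", 9)
        for p in grid:
            assert bernoulli_sensitivity(longer, p) >= bernoulli_sensitivity(vec, p)


class TestMonomialIntegral:
    def test_beta_function_cases(self):
        assert integrate_monomial(2, 1, 0, 1) == Fraction(1, 12)
        assert integrate_monomial(0, 0, Fraction(1, 4), Fraction(3, 4)) == Fraction(1, 2)

    @pytest.mark.parametrize("l", [4, 8, 12])
    def test_full_interval_closed_form(self, l):
        for m in range(l + 1):
            assert integrate_monomial(m, l - m, 0, 1) == Fraction(1, (l + 1) * comb(l, m))

    def test_against_numerical_quadrature(self):
        for u, v, a, b in [(3, 2, 0, 1), (2, 5, Fraction(1, 5), Fraction(4, 5)), (0, 7, 0, Fraction(1, 2))]:
            num, _ = quad(lambda p: p**u * (1 - p) ** v, float(a), float(b))
            assert abs(float(integrate_monomial(u, v, a, b)) - num) < 1e-12

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            integrate_monomial(1, 1, Fraction(1, 2), Fraction(1, 2))


class TestHitIntegration:
    def test_full_interval_equals_mean_of_dirac(self):
        vec = count_coefficients("1101", 7)
        hi = hit_integration(vec, 0, 1)
        mean_dirac = sum(dirac(vec, m) for m in range(8)) / 8
        assert hi == mean_dirac  # exact rational identity

    def test_mean_value_property(self):
        vec = count_coefficients("101", 6)
        a, b = Fraction(2, 10), Fraction(8, 10)
        hi = hit_integration(vec, a, b)
        samples = [bernoulli_sensitivity(vec, a + (b - a) * Fraction(i, 16)) for i in range(17)]
        assert min(samples) <= hi <= max(samples)

    def test_degenerate_vectors(self):
        empty = count_coefficients("11111111111", 8)  # span > l: nothing detected
        assert hit_integration(empty, 0, 1) == 0
        full = count_coefficients("1", 4)
        # '1' misses only the all-mismatch string; add it back for the full vector check
        assert hit_integration(full, 0, 1) < 1
        assert hit_integration(full, 0, 1) == Fraction(1, 5) * sum(
            Fraction(c, comb(4, m)) for m, c in enumerate(full.coefficients)
        )


class TestDiracHeaviside:
    def test_dirac_examples(self):
        vec = count_coefficients("1101", 4)
        assert dirac(vec, 4) == 1
        assert dirac(vec, 3) == Fraction(1, 4)
        assert dirac(vec, 2) == 0  # below the seed weight

    def test_heaviside_examples(self):
        vec = count_coefficients("1101", 4)
        assert heaviside(vec, 3, 4) == Fraction(5, 8)
        assert heaviside(vec, 2, 2) == dirac(vec, 2)  # degenerate window

    def test_heaviside_full_window_is_mean_dirac(self):
        vec = count_coefficients("101", 6)
        assert heaviside(vec, 0, 6) == hit_integration(vec, 0, 1)

    def test_range_validation(self):
        vec = count_coefficients("11", 4)
        with pytest.raises(ValueError):
            dirac(vec, 5)
        with pytest.raises(ValueError):
            heaviside(vec, 3, 2)


class TestFrequencyConvention:
    @pytest.mark.parametrize(
        "f, l, m", [(Fraction(1, 2), 64, 32), (1, 10, 10), (Fraction(33, 100), 10, 3)]
    )
    def test_floor_convention(self, f, l, m):
        assert frequency_to_count(f, l) == m

    def test_pair_form(self):
        assert frequency_to_counts(Fraction(1, 2), 1, 64) == (32, 64)
        with pytest.raises(ValueError):
            frequency_to_counts(Fraction(1, 2), Fraction(1, 2), 64)


class TestLossless:
    def test_worked_lossless_values(self):
        """1101 detects every single-mismatch alignment from l=6 on; at l=5
        the undetected alignment 10111 is the witness."""
        assert lossless_tropical("1101", 6, 1) == (True, None)
        ok, witness = lossless_tropical("1101", 5, 1)
        assert not ok
        assert witness == "10111"

    def test_witness_is_genuinely_undetected(self):
        from spacedseeds import hits

        ok, witness = lossless_tropical("1101", 5, 1)
        assert witness.count("0") <= 1
        assert not hits(SeedSet.of("1101"), witness)

    def test_contiguous_pair_trivial_case(self):
        assert lossless_tropical("11", 2, 0) == (True, None)

    @pytest.mark.parametrize("pattern", ["1101", "101"])
    def test_dual_route_equivalence(self, pattern):
        """Tropical DP and binomial tail equality always agree."""
        for l in range(4, 11):
            vec = count_coefficients(pattern, l)
            for k in range(0, 4):
                trop, _ = lossless_tropical(pattern, l, k)
                assert trop == lossless_from_coefficients(vec, k)

    def test_k_above_length_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            ok, _ = lossless_tropical("1", 2, 5)
        assert not ok  # the all-mismatch alignment is never hit by '1'
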