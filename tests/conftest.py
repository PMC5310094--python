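from fractions import Fraction

import pytest
from hypothesis import settings

import spacedseeds as sp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

PH1 = "111010010100110111"        # Patternhunter I, weight 11, span 18
CONTIG11 = "11111111111"          # contiguous weight-11 seed


@pytest.fixture(scope="session")
def ph1_vec64() -> sp.CoefficientVector:
    return sp.count_coefficients(PH1, 64)


@pytest.fixture(scope="session")
def contig11_vec64() -> sp.CoefficientVector:
    return sp.count_coefficients(CONTIG11, 64)


@pytest.fixture(scope="session")
def p07() -> Fraction:
    return Fraction(7, 10)
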