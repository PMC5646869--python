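from fractions import Fraction

import pytest

from methylkl import MethylationSite


@pytest.fixture
def toy_sites():
    """3-site toy methylome {(T,M)} = {(2,2),(2,0),(4,2)}; p = 1/2."""
    return [
        MethylationSite("chr1", 2, "+", 2, 2),
        MethylationSite("chr1", 10, "+", 0, 2),
        MethylationSite("chr1", 20, "+", 2, 4),
    ]


@pytest.fixture
def toy_reference():
    return {"chrT": "TACGGA"}


# Frozen oracle values for the toy methylome, computed by independent
# brute-force binomial enumeration (exact rationals, then float log2).
TOY_P = Fraction(1, 2)
TOY_RRAN = {
    Fraction(0): Fraction(3, 16),
    Fraction(1, 4): Fraction(1, 12),
    Fraction(1, 2): Fraction(11, 24),
    Fraction(3, 4): Fraction(1, 12),
    Fraction(1): Fraction(3, 16),
}
TOY_KL0 = 0.2766916662
TOY_KL1 = 0.2766916662
TOY_D0 = 0.1458333333
TOY_D1 = 0.1458333333
TOY_KL_FULL = 0.4002394596
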