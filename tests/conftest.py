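import pytest

from splicequant import (
    KRAS_2_35_G12V,
    EnumerationConfig,
    FragmentConfig,
    Tolerance,
)

SPLICED = "KLVVGAVGV"  # [KL][VVGAVGV], splice reactants at 5-6 and 8-14
NONSPLICED = "KLVVVGAVG"  # contiguous 5-13


@pytest.fixture
def kras():
    return KRAS_2_35_G12V


@pytest.fixture
def enum9():
    """Enumeration restricted to 9-mers (the length of both targets)."""
    return EnumerationConfig(min_len=9, max_len=9)


@pytest.fixture
def frag_by_z1():
    """b/y only, singly charged, no losses — the figure-style ion set."""
    return FragmentConfig(series=("b", "y"), losses=(), max_charge=1)


@pytest.fixture
def tol20ppm():
    return Tolerance("ppm", 20.0)


@pytest.fixture
def tol002da():
    return Tolerance("Da", 0.02)
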