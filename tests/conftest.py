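from fractions import Fraction

import pytest
from hypothesis import settings

from sawtube import enumerate_walks, get_lattice
from sawtube.lattice import TubeRegion

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def region(lattice_name: str, n=None) -> TubeRegion:
    return TubeRegion(get_lattice(lattice_name), None if n is None else Fraction(n))


#: the nine studied tube sizes
TUBE_SIZES = [
    ("SC", Fraction(1)),
    ("SC", Fraction(2)),
    ("SC", Fraction(3)),
    ("FCC", Fraction(1, 2)),
    ("FCC", Fraction(1)),
    ("FCC", Fraction(3, 2)),
    ("FCC", Fraction(2)),
    ("FCC", Fraction(5, 2)),
    ("FCC", Fraction(3)),
]


@pytest.fixture(scope="session")
def sc1_census_17():
    """Full census of the 1x1 SC tube from its corner origin, N <= 17."""
    return enumerate_walks(region("SC", 1), (0, 0, 0), 17)


@pytest.fixture(scope="session")
def fcc05_census_12():
    """Full census of the 0.5*sqrt2 FCC tube from its corner origin, N <= 12."""
    return enumerate_walks(region("FCC", Fraction(1, 2)), (0, 0, 0), 12)


@pytest.fixture(scope="session")
def sc2_census_17():
    """Census of the 2x2 SC tube, corner (type 1) origin, N <= 17."""
    return enumerate_walks(region("SC", 2), (0, 0, 0), 17)
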