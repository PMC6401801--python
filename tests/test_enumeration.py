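from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sawtube import (
    census_merge,
    classify_origins,
    enumerate_walks,
    get_lattice,
    oracle_enumerate,
)

from conftest import region

# published leading terms of the unrestricted series
SC_SERIES = [6, 30, 150, 726, 3534]
FCC_SERIES = [12, 132, 1404, 14700, 152532]


@pytest.mark.parametrize("engine", ["python", "numba"])
@pytest.mark.parametrize(
    "lat,series", [("SC", SC_SERIES), ("FCC", FCC_SERIES)]
)
def test_unrestricted_series(lat, series, engine):
    n = len(series)
    census = enumerate_walks(region(lat), (0, 0, 0), n, engine=engine)
    assert [census.counts[i] for i in range(1, n + 1)] == series
    z = get_lattice(lat).coordination
    assert census.counts[1] == z
    assert census.counts[2] == z * (z - 1)


def test_confined_first_step_count():
    # corner of the 1x1 SC tube: 2 of the 6 steps leave the tube
    census = enumerate_walks(region("SC", 1), (0, 0, 0), 1)
    assert census.counts == {1: 4}


@pytest.mark.parametrize(
    "lat,n",
    [("SC", 1), ("SC", 2), ("SC", 3),
     ("FCC", Fraction(1, 2)), ("FCC", 1), ("FCC", Fraction(3, 2))],
)
def test_oracle_equivalence_small_lengths(lat, n):
    """DFS census equals generate-and-filter for every origin class, N <= 4."""
    r = region(lat, n)
    for cls in classify_origins(r):
        fast = enumerate_walks(r, cls.representative, 4, engine="numba")
        slow = oracle_enumerate(r, cls.representative, 4)
        assert fast.counts == slow.counts
        assert fast.e2e_hist == slow.e2e_hist


def test_engines_agree():
    r = region("FCC", 1)
    a = enumerate_walks(r, (0, 0, 0), 6, engine="python")
    b = enumerate_walks(r, (0, 0, 0), 6, engine="numba")
    assert a.counts == b.counts and a.e2e_hist == b.e2e_hist


def test_census_identical_across_class_members():
    r = region("SC", 2)
    for cls in classify_origins(r):
        censuses = [enumerate_walks(r, s, 6) for s in cls.sites]
        for c in censuses[1:]:
            assert c.counts == censuses[0].counts
            assert c.e2e_hist == censuses[0].e2e_hist


def test_counts_monotone_in_origin_type_and_confinement():
    r = region("SC", 2)
    per_type = [
        enumerate_walks(r, cls.representative, 8) for cls in classify_origins(r)
    ]
    unrestricted = enumerate_walks(region("SC"), (0, 0, 0), 8)
    for n in range(1, 9):
        counts = [c.counts[n] for c in per_type]
        assert counts == sorted(counts)  # less confined => no fewer walks
        assert counts[-1] <= unrestricted.counts[n]


def test_histogram_totals_and_support(sc1_census_17):
    census = sc1_census_17
    sq = get_lattice(census.lattice_name).step_sq_internal
    for n in range(1, census.n_max + 1):
        hist = census.e2e_hist[n]
        assert sum(hist.values()) == census.counts[n]
        assert min(hist) >= sq  # physical omega^2 >= 1
        assert max(hist) <= n * n * sq  # physical omega^2 <= N^2
        assert census.counts[n] > 0


def test_mean_sq_e2e_is_exact_rational(fcc05_census_12):
    m = fcc05_census_12.mean_sq_e2e(12)
    assert isinstance(m, Fraction)
    assert 1 <= m <= 144


@given(st.integers(0, 5), st.integers(0, 1), st.integers(0, 1))
def test_axial_translation_leaves_census_invariant(x1, x2, x3):
    r = region("SC", 1)
    base = enumerate_walks(r, (0, x2, x3), 4)
    moved = enumerate_walks(r, (x1, x2, x3), 4)
    assert moved.counts == base.counts and moved.e2e_hist == base.e2e_hist


def test_merge_of_first_step_partition_equals_monolithic():
    r = region("SC", 2)
    whole = enumerate_walks(r, (0, 0, 0), 8)
    parts = [
        enumerate_walks(r, (0, 0, 0), 8, first_steps=(k,)) for k in range(6)
    ]
    merged = census_merge(parts)
    assert merged.counts == whole.counts
    assert merged.e2e_hist == whole.e2e_hist


def test_merge_single_full_part_is_identity():
    c = enumerate_walks(region("SC", 1), (0, 0, 0), 5)
    m = census_merge([c])
    assert m.counts == c.counts and m.e2e_hist == c.e2e_hist


def test_merge_rejects_bad_partitions():
    r = region("SC", 1)
    p0 = enumerate_walks(r, (0, 0, 0), 3, first_steps=(0, 1, 2))
    with pytest.raises(ValueError, match="do not cover"):
        census_merge([p0])
    p_dup = enumerate_walks(r, (0, 0, 0), 3, first_steps=(2, 3, 4, 5))
    with pytest.raises(ValueError, match="overlap"):
        census_merge([p0, p0, p_dup])
    other = enumerate_walks(r, (0, 0, 0), 4)
    with pytest.raises(ValueError, match="incompatible"):
        census_merge([p0, other])
    with pytest.raises(ValueError, match="empty"):
        census_merge([])


def test_input_validation():
    r = region("SC", 1)
    with pytest.raises(ValueError, match="outside"):
        enumerate_walks(r, (0, 5, 0), 3)
    with pytest.raises(ValueError, match="n_max"):
        enumerate_walks(r, (0, 0, 0), 0)
    with pytest.raises(ValueError, match="lattice site"):
        enumerate_walks(region("FCC", 1), (0, 1, 0), 3)
    with pytest.raises(ValueError, match="n <= 6"):
        oracle_enumerate(r, (0, 0, 0), 7)
    with pytest.raises(ValueError, match="first-step"):
        enumerate_walks(r, (0, 0, 0), 3, first_steps=(9,))
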