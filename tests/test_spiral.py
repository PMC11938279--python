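import math

import pytest
from hypothesis import given, settings, strategies as st

from conftest import adj_to_graph, brute_force_canonical_codes, relabel_dual_adj
from fullertk._spiralkernels import canonical_code_py, windup_adj_py
from fullertk.embedding import ValidationError
from fullertk.spiral import (
    SpiralCode,
    SpiralRejection,
    acceptance_rate,
    enumerate_codes,
    isomer_by_index,
    isomer_count,
    rank_pentagon_vector,
    sample_many,
    unrank_pentagon_vector,
    unwind_canonical,
    windup,
    windup_adjacency,
    windup_dual,
)


def test_dodecahedron_windup():
    code = SpiralCode(20, tuple(range(1, 13)))
    f = windup(code)
    assert f.n == 20
    assert unwind_canonical(f) == code


def test_clustered_pentagons_rejected_at_n60():
    with pytest.raises(SpiralRejection):
        windup(SpiralCode(60, tuple(range(1, 13))))


def test_malformed_codes_rejected():
    with pytest.raises(ValidationError):
        SpiralCode(20, tuple(range(1, 12)))  # 11 positions
    with pytest.raises(ValidationError):
        SpiralCode(20, (1, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11))  # repeated


@pytest.mark.parametrize("n,count", [(20, 1), (22, 0), (24, 1), (26, 1), (28, 2)])
def test_enumeration_against_bruteforce_oracle(n, count):
    codes = list(enumerate_codes(n)) if n != 22 else []
    assert len(codes) == count
    if n != 22:
        assert codes == brute_force_canonical_codes(n)


def test_known_small_isomer_counts():
    # census values for small n, independently established in the literature
    expected = {30: 3, 32: 6, 34: 6, 36: 15, 38: 17, 40: 40}
    for n, c in expected.items():
        assert isomer_count(n) == c


def test_enumeration_is_sorted_and_canonical():
    codes = enumerate_codes(32)
    assert list(codes) == sorted(codes)
    for code in codes:
        assert unwind_canonical(windup(code)) == code


@pytest.mark.parametrize("n", [20, 24, 26, 28, 30, 32, 34, 36, 38, 40])
def test_spiral_roundtrip_all_isomers(n):
    """unwind_canonical(windup(code)) == code over every enumerated isomer."""
    for code in enumerate_codes(n):
        assert unwind_canonical(windup(code)) == code


def test_canonical_code_is_relabelling_invariant():
    for code in enumerate_codes(28):
        adj = windup_adjacency(code)
        degs = [len(s) for s in adj]
        base = canonical_code_py(adj, degs)
        for seed in (1, 2):
            r = relabel_dual_adj(adj, seed)
            assert canonical_code_py(r, [len(s) for s in r]) == base


def test_isomer_by_index():
    f = isomer_by_index((20, 1))
    assert f.n == 20
    with pytest.raises(ValidationError):
        isomer_by_index((20, 2))


def test_unrank_extremes():
    assert unrank_pentagon_vector(1, 32) == tuple(range(1, 13))
    assert unrank_pentagon_vector(math.comb(32, 12), 32) == tuple(range(21, 33))


@settings(derandomize=True, max_examples=200)
@given(st.integers(min_value=1, max_value=math.comb(32, 12)))
def test_rank_unrank_bijection(N):
    assert rank_pentagon_vector(unrank_pentagon_vector(N, 32), 32) == N


@settings(derandomize=True, max_examples=50)
@given(st.sets(st.integers(1, 40), min_size=12, max_size=12))
def test_unrank_rank_inverse(positions):
    tup = tuple(sorted(positions))
    assert unrank_pentagon_vector(rank_pentagon_vector(tup, 40), 40) == tup


def test_sampler_returns_valid_isomers():
    codes, trials = sample_many(24, 5, rng_seed=7)
    assert trials >= 5
    for code in codes:
        assert code == unwind_canonical(windup(code))


def test_acceptance_rate_conventions():
    # face-count convention: iso(28)/C(16,12)
    assert math.isclose(acceptance_rate(28), isomer_count(28) / math.comb(16, 12))
    # the historical length-n dialect reproduces the ~1e-9 figure at n = 60
    rate = acceptance_rate(60, convention="vertices")
    assert 1e-10 < rate < 1e-8


def test_kernel_matches_python_reference():
    """numba enumeration agrees with the pure-Python oracle path at n=30."""
    codes = enumerate_codes(30)
    for code in codes:
        adj = windup_adj_py(code.sizes)
        assert adj is not None
        assert canonical_code_py([set(s) for s in adj], list(code.sizes)) == code.sizes
    g = adj_to_graph(windup_adjacency(codes[0]))
    assert g.number_of_edges() == 3 * 17 - 6  # 3m - 6 triangulation edges
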