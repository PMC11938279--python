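import pytest
import sympy

from fullertk.embedding import ValidationError
from fullertk.fullerene import (
    PentagonPartition,
    count_integer_partitions,
    dualize,
    dualize_inverse,
    is_feasible,
    is_ipr,
    pentagon_partition,
    subgraph5,
    subgraph6,
)
from fullertk.spiral import enumerate_codes, unwind_canonical, windup, windup_dual


def test_feasibility():
    assert is_feasible(20) and is_feasible(60)
    assert not is_feasible(22) and not is_feasible(21) and not is_feasible(18)


def test_c20_dual_is_icosahedron(c20_dual, icosahedron_graph):
    import networkx as nx

    assert c20_dual.m == 12
    assert nx.is_isomorphic(c20_dual.graph(), icosahedron_graph)


@pytest.mark.parametrize("n", [20, 24, 28, 30, 36])
def test_face_and_degree_census(n):
    for code in enumerate_codes(n):
        f = windup(code)
        assert f.n == n
        assert f.embedding.num_edges == 3 * n // 2
        t = dualize(f)
        degs = t.embedding.degrees()
        assert degs.count(5) == 12
        assert degs.count(6) == n // 2 - 10
        assert subgraph5(t).number_of_nodes() == 12
        assert subgraph6(t).number_of_nodes() == n // 2 - 10


def test_dualize_roundtrip_small():
    for n in (20, 24, 26, 28, 30):
        for code in enumerate_codes(n):
            f = windup(code)
            back = dualize_inverse(dualize(f))
            assert unwind_canonical(back) == code


def test_pentagon_partition_examples(c20_dual):
    assert pentagon_partition(c20_dual).parts == (12,)
    # all parts always sum to 12
    for n in (24, 28, 32):
        for code in enumerate_codes(n):
            parts = pentagon_partition(windup_dual(code)).parts
            assert sum(parts) == 12
            assert list(parts) == sorted(parts, reverse=True)


def test_no_ipr_below_60():
    for n in range(20, 60, 2):
        if n == 22:
            continue
        assert not any(
            is_ipr(windup_dual(c)) for c in enumerate_codes(n)
        ), f"unexpected IPR isomer at n={n}"


def test_unique_ipr_c60_is_isomer_1812():
    codes = enumerate_codes(60)
    ipr = [j for j, c in enumerate(codes, start=1) if is_ipr(windup_dual(c))]
    assert ipr == [1812]


def test_ipr_subgraph5_edgeless():
    t = windup_dual(enumerate_codes(60)[1811])
    assert subgraph5(t).number_of_edges() == 0


def test_partition_validation():
    with pytest.raises(ValidationError):
        PentagonPartition((5, 5, 5))
    with pytest.raises(ValidationError):
        PentagonPartition((1, 11))  # not sorted non-increasing


@pytest.mark.parametrize("k,expected", [(1, 1), (5, 7), (12, 77)])
def test_count_integer_partitions(k, expected):
    assert count_integer_partitions(k) == expected


def test_partition_counts_match_sympy():
    from sympy.functions.combinatorial.numbers import partition

    for k in range(1, 30):
        assert count_integer_partitions(k) == partition(k)
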