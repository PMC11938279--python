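import collections

import networkx as nx
import pytest

from fullertk.embedding import ValidationError, trace_faces
from fullertk.families import (
    bipyramid_seed,
    chamfer,
    construction2,
    construction3,
    goldberg,
    hexagonal_subgraph_counts,
    nanotube_5_0,
    t_triangle,
    truncated_triangle,
)
from fullertk.fullerene import dualize, is_ipr, pentagon_partition
from fullertk.spiral import enumerate_codes, unwind_canonical
from fullertk.transforms import has_gsw_path


@pytest.mark.parametrize("t", [0, 1, 2, 3, 4])
def test_t_triangle_census(t):
    tc = t_triangle(t)
    assert tc.num_vertices == (t + 1) * (t + 2) // 2
    assert tc.inner_triangle_count() == t * t
    degs = collections.Counter(tc.graph.degrees())
    if t > 0:
        assert degs[2] == 3
        assert degs[4] == 3 * (t - 1)
        assert degs[6] == tc.num_vertices - 3 - 3 * (t - 1)


def test_truncated_triangle_examples():
    # untruncated fallback
    assert truncated_triangle(3, 0, 0, 0).num_vertices == t_triangle(3).num_vertices
    tt = truncated_triangle(4, 1, 0, 0)
    assert tt.num_vertices == 15 - 1
    assert tt.inner_triangle_count() == 16 - 1
    assert len(tt.open_edges) == 1 and len(tt.cut_rows) == 1
    piece = truncated_triangle(4, 1, 1, 1)
    assert piece.num_vertices == 12
    assert piece.inner_triangle_count() == 13  # 4t^2 - 3(t-1)^2 at t = 2
    with pytest.raises(ValidationError):
        truncated_triangle(4, 2, 2, 0)  # r_i + r_j > t - 1
    with pytest.raises(ValidationError):
        truncated_triangle(3, 0, 1, 0)  # not sorted


def test_truncated_vertex_count_closed_form():
    for t in (2, 3, 4):
        tc = truncated_triangle(2 * t, t - 1, t - 1, t - 1)
        expected = (2 * t + 1) * (t + 1) - 3 * t * (t - 1) // 2
        assert tc.num_vertices == expected


@pytest.mark.parametrize("t", [2, 3])
def test_construction2_family(t):
    d = construction2(t)
    d.validate()
    assert d.n == 4 * (t * t + 6 * t + 7)
    assert pentagon_partition(d).parts == (3, 3, 3, 3)
    assert not has_gsw_path(d)


def test_construction2_hexagonal_subgraph_t2():
    hexes, tris, verts = hexagonal_subgraph_counts(2)
    assert hexes == 4
    assert tris == 4 * 13  # t^2 + 6t - 3 triangles per glued piece
    assert verts == 2 * (4 + 12 + 2)


def test_construction2_rejects_small_t():
    with pytest.raises(ValidationError):
        construction2(1)


def test_construction3_seed_is_c36_1():
    assert unwind_canonical(construction3(36)) == enumerate_codes(36)[0]


@pytest.mark.parametrize("n", [38, 40, 60, 100])
def test_construction3_range(n):
    f = construction3(n)
    f.validate()
    assert f.n == n


def test_construction3_rejects_bad_n():
    for n in (34, 37):
        with pytest.raises(ValidationError):
            construction3(n)


def test_nanotube_endpoints():
    f20 = nanotube_5_0(20)
    assert unwind_canonical(f20) == enumerate_codes(20)[0]
    f60 = nanotube_5_0(60)
    f60.validate()
    assert f60.n == 60
    # cap structure: two groups of six degree-5 vertices in the dual
    t = dualize(f60)
    degs = t.embedding.degrees()
    assert degs.count(5) == 12
    with pytest.raises(ValidationError):
        nanotube_5_0(24)


def test_goldberg_counts_and_ipr():
    assert goldberg(1, 0).n == 20
    g11 = goldberg(1, 1)
    assert g11.n == 60 and is_ipr(dualize(g11))
    assert unwind_canonical(g11) == enumerate_codes(60)[1811]  # C60,1812
    assert goldberg(2, 1).n == 140
    with pytest.raises(ValidationError):
        goldberg(0, 0)


def test_chamfer_is_goldberg_doubling(c20_dual):
    t80 = chamfer(c20_dual)
    assert t80.n == 80
    assert nx.is_isomorphic(t80.graph(), dualize(goldberg(2, 0)).graph())


def test_bipyramid_seed_structure():
    bp = bipyramid_seed(5)
    assert sorted(bp.degrees()) == [3, 3, 4, 4, 4]
    bp12 = bipyramid_seed(12)
    degs = collections.Counter(bp12.degrees())
    assert degs[10] == 2 and degs[4] == 10
    # same vertex/edge/face counts as a C20 dual-sized triangulation
    assert bp12.num_vertices == 12
    assert bp12.num_edges == 3 * 12 - 6
    assert all(len(f) == 3 for f in trace_faces(bp12))
    with pytest.raises(ValidationError):
        bipyramid_seed(4)
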