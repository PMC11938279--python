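import collections

import networkx as nx
import pytest

from fullertk.cutpartition import (
    classify_facet_vertices,
    conjecture2_scan,
    cut_partition,
    hexagonal_rotation,
    recognize_component,
)
from fullertk.families import chamfer, construction2, goldberg, t_triangle, truncated_triangle
from fullertk.fullerene import dualize
from fullertk.spiral import enumerate_codes, windup_dual
from fullertk.transforms import has_gsw_path


def test_isolated_triangle_has_no_facet_vertices():
    tc = t_triangle(3)
    rot = {v: list(nbrs) for v, nbrs in enumerate(tc.graph.rotation)}
    labels = classify_facet_vertices(rot)
    assert set(labels.values()) == {"none"}


def test_two_facet_vertices_of_c56_622():
    t = windup_dual(enumerate_codes(56)[621])
    labels = classify_facet_vertices(t)
    counts = collections.Counter(labels.values())
    # four corner-sharing 2-triangles: six shared (degree-4) vertices
    assert counts["two_facet"] == 6
    assert counts["three_facet"] == 0


def test_cut_partition_c56_622_four_2_triangles():
    t = windup_dual(enumerate_codes(56)[621])
    cp = cut_partition(t)
    assert cp.classifications == [("t_triangle", 2)] * 4
    assert cp.duplications == 6
    # vertex conservation
    assert sum(cp.sizes) == len(hexagonal_rotation(t)) + cp.duplications


def test_cut_partition_c20_empty(c20_dual):
    cp = cut_partition(c20_dual)
    assert cp.components == [] and cp.classifications == []


def test_cut_partition_goldberg80_twenty_1_triangles():
    cp = cut_partition(dualize(goldberg(2, 0)))
    assert collections.Counter(cp.classifications) == {("t_triangle", 1): 20}


def test_cut_partition_chamfered_c24(c24_dual):
    """The n=96 counterexample: 12 single 1-triangles plus two groups that
    each slit into a 3-triangle and three further 1-triangles."""
    cp = cut_partition(chamfer(c24_dual))
    assert collections.Counter(cp.classifications) == {
        ("t_triangle", 1): 18,
        ("t_triangle", 3): 2,
    }


def test_cut_partition_construction2():
    cp = cut_partition(construction2(2))
    assert cp.classifications == [("truncated", 4, (1, 1, 1))] * 4


def test_recognize_component_examples():
    assert recognize_component(nx.Graph({0: []})) == ("t_triangle", 0)
    assert recognize_component(t_triangle(2).graph.to_networkx()) == (
        "t_triangle", 2,
    )
    tt = truncated_triangle(4, 1, 0, 0)
    assert recognize_component(tt.graph.to_networkx()) == ("truncated", 4, (1, 0, 0))
    assert recognize_component(nx.path_graph(2)) == ("other",)
    assert recognize_component(nx.cycle_graph(6)) == ("other",)


def test_conjecture2_scan_small():
    df = conjecture2_scan(36)
    assert bool(df["agree"].all())
    # C20 partitions trivially; exception clause applies
    row20 = df[(df.n == 20)].iloc[0]
    assert bool(row20.only_zero_triangles) and not bool(row20.has_gsw_path)
    # everything else in this range has a gSW path
    assert bool(df[df.n > 20]["has_gsw_path"].all())
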