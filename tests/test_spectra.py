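import math
from itertools import product

import mpmath
import networkx as nx
import numpy as np
import pytest

from conftest import adj_to_graph, relabel_dual_adj
from fullertk.embedding import ValidationError
from fullertk.fullerene import dualize
from fullertk.families import goldberg, nanotube_5_0
from fullertk.spectra import (
    CharacterParams,
    character,
    character_expm,
    newton_polynomial,
    normalized_character,
    riemann_zeta,
    spectrum,
    zeta_tail_bound,
)
from fullertk.spiral import enumerate_codes, windup_adjacency, windup_dual


def brute_force_closed_walks(g: nx.Graph, k: int) -> int:
    """Count closed k-walks by explicit path extension (oracle)."""
    nodes = list(g.nodes)
    total = 0
    for start in nodes:
        stack = [(start, 0)]
        while stack:
            v, depth = stack.pop()
            if depth == k:
                total += v == start
                continue
            stack.extend((w, depth + 1) for w in g.neighbors(v))
    return total


def test_newton_polynomial_order_0_and_2(c20_dual):
    assert newton_polynomial(c20_dual, 0) == pytest.approx(12)
    assert newton_polynomial(c20_dual, 2) == pytest.approx(60)  # 2|E|


@pytest.mark.parametrize("k", [3, 4, 5])
def test_newton_equals_walk_counts(c20_dual, k):
    g = c20_dual.graph()
    assert newton_polynomial(c20_dual, k) == pytest.approx(
        brute_force_closed_walks(g, k)
    )


def test_newton_triangle_count(c24_dual):
    g = c24_dual.graph()
    triangles = sum(nx.triangles(g).values()) // 3
    assert newton_polynomial(c24_dual, 3) == pytest.approx(6 * triangles)


def test_icosahedron_closed_form_spectrum(c20_dual):
    """Adjacency eigenvalues 5, +-sqrt(5) (x3 each), -1 (x5), shifted by
    (beta/alpha) * 5 for the constant degree."""
    p = CharacterParams(0.5, 0.25)
    lam = spectrum(c20_dual, p)
    s5 = math.sqrt(5)
    expected = np.sort(np.array([5] + [s5] * 3 + [-s5] * 3 + [-1] * 5) + 0.5 * 5)
    assert np.allclose(lam, expected, atol=1e-9)
    assert character(c20_dual, p) == pytest.approx(
        float(np.sum(np.exp(p.alpha * expected))), rel=1e-12
    )


def test_character_equals_trace_of_expm():
    for n, (a, b) in product((24, 28), ((0.5, 0.25), (1.0, 1.0), (1.0, 0.0))):
        for code in enumerate_codes(n):
            t = windup_dual(code)
            p = CharacterParams(a, b) if a else None
            ce = character(t, CharacterParams(a, b))
            assert ce == pytest.approx(
                character_expm(t, CharacterParams(a, b)), rel=1e-9
            )


def test_character_limit_is_vertex_count():
    for n in (20, 24, 28):
        t = windup_dual(enumerate_codes(n)[0])
        small = CharacterParams(1e-8, 1e-8)
        assert abs(character(t, small) - t.m) < 1e-6


def test_character_is_relabelling_invariant():
    adj = windup_adjacency(enumerate_codes(28)[0])
    base = character(adj_to_graph(adj))
    for seed in (3, 4):
        r = relabel_dual_adj(adj, seed)
        assert character(adj_to_graph(r)) == pytest.approx(base, rel=1e-12)


def test_normalized_character_extremes():
    assert normalized_character(dualize(goldberg(1, 1)), 60) == pytest.approx(0.0)
    assert normalized_character(dualize(nanotube_5_0(60)), 60) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        normalized_character(dualize(goldberg(1, 1)), 62)


def test_character_histogram_support_and_bins():
    from fullertk.spectra import character_histogram

    for choice in ("dual", "hexagonal-subgraph"):
        hist, edges = character_histogram(60, graph_choice=choice, bins=250)
        assert len(hist) == 250 and len(edges) == 251
        assert edges[0] == 0.0 and edges[-1] == 1.0
        # density normalization over [0, 1]
        width = edges[1] - edges[0]
        assert float(np.sum(hist) * width) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        character_histogram(60, graph_choice="primal")


def test_invalid_params_rejected():
    with pytest.raises(ValidationError):
        CharacterParams(0.0, 1.0)


@pytest.mark.parametrize("s,ref", [(2, math.pi**2 / 6), (4, math.pi**4 / 90)])
def test_zeta_closed_forms(s, ref):
    assert riemann_zeta(s) == pytest.approx(ref, rel=1e-12)


def test_zeta_matches_mpmath_and_bound():
    for s in (1.5, 3, 9, 12):
        assert riemann_zeta(s) == pytest.approx(float(mpmath.zeta(s)), rel=1e-10)
    # integral-test remainder bound really bounds the truncation error
    for s, k in ((2, 1000), (9, 10)):
        partial = sum(i ** (-s) for i in range(1, k + 1))
        assert abs(riemann_zeta(s) - partial) <= zeta_tail_bound(s, k)
    with pytest.raises(ValidationError):
        riemann_zeta(1.0)
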