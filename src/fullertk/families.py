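"""Deterministic generators for named fullerene families.

* triangular-lattice patches (*t-triangles* and corner-truncated
  ``(t, (r1, r2, r3))``-triangles), the building blocks of cut-partitions;
* the tetrahedrally glued gSW-free family (four truncated triangles plus
  four pentagonal 1-triangles), which realizes fullerenes with
  ``n = 4(t^2 + 6t + 7)`` on which no gSW path exists;
* an iterative seed construction producing one isomer for every feasible
  ``n >= 36`` by growing a fixed boundary pattern one dual vertex at a time;
* (5,0)-nanotubes, Goldberg polyhedra and the bipyramid (prism-dual) seed
  used by random flip walks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull

from .embedding import PlanarEmbedding, ValidationError, embedding_from_graph, trace_faces
from .fullerene import DualTriangulation, Fullerene, dualize, dualize_inverse
from .spiral import enumerate_codes, windup_dual

__all__ = [
    "TriangleComponent",
    "t_triangle",
    "truncated_triangle",
    "construction2",
    "construction3",
    "nanotube_5_0",
    "goldberg",
    "chamfer",
    "bipyramid_seed",
]


# --------------------------------------------------------------------------
# triangular-lattice patches
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangleComponent:
    """A (possibly corner-truncated) triangular patch of the hexagonal dual.

    An untruncated *t-triangle* is the triangular grid with ``t + 1`` rows:
    ``(t+1)(t+2)/2`` vertices, ``t^2`` inner triangular faces, three corners
    of degree 2 and ``3(t-1)`` side vertices of degree 4.  Truncation removes
    the ``r_i`` rows nearest each corner (``r_i(r_i+1)/2`` vertices and
    ``r_i^2`` inner triangles); edges between vertices whose degree dropped
    are the *open edges* along which patches are glued.
    """

    t: int
    truncation: tuple[int, int, int]
    graph: PlanarEmbedding
    open_edges: tuple[tuple[int, int], ...]
    # cut rows (one ordered vertex tuple per truncated corner), for gluing
    cut_rows: tuple[tuple[int, ...], ...]

    @property
    def num_vertices(self) -> int:
        return self.graph.num_vertices

    def inner_triangle_count(self) -> int:
        # all inner faces of a (truncated) lattice patch are triangles; only
        # the single outer face is excluded (it is itself a triangle at t=1)
        if self.graph.num_edges == 0:
            return 0
        return len(trace_faces(self.graph)) - 1


def _grid_vertices(t: int):
    return [(i, j) for i in range(t + 1) for j in range(i + 1)]


def _grid_rotation(keep: set, t: int):
    """CCW rotation for the triangular grid restricted to ``keep``."""
    order = [(0, 1), (-1, 0), (-1, -1), (0, -1), (1, 0), (1, 1)]
    rot = {}
    for (i, j) in keep:
        nbrs = []
        for di, dj in order:
            q = (i + di, j + dj)
            if q in keep:
                nbrs.append(q)
        rot[(i, j)] = nbrs
    return rot


def t_triangle(t: int) -> TriangleComponent:
    """Untruncated triangular patch of side ``t`` (single vertex for t=0)."""
    return truncated_triangle(t, 0, 0, 0)


def truncated_triangle(t: int, r1: int, r2: int, r3: int) -> TriangleComponent:
    """``(t, (r1, r2, r3))``-triangle with open edges marked.

    Corners are ordered (top, bottom-left, bottom-right); ``r1 >= r2 >= r3``
    and ``r_i + r_j <= t - 1`` for ``i != j`` so the cuts never meet.
    """
    if t < 0:
        raise ValidationError("t must be >= 0")
    rs = (r1, r2, r3)
    if any(r < 0 for r in rs) or not (r1 >= r2 >= r3):
        raise ValidationError(f"need r1 >= r2 >= r3 >= 0, got {rs}")
    if t > 0 and any(rs[i] + rs[j] > t - 1 for i in range(3) for j in range(i + 1, 3)):
        raise ValidationError(f"truncations overlap: t={t}, r={rs}")
    if t == 0 and any(rs):
        raise ValidationError("cannot truncate a single vertex")
    full = set(_grid_vertices(t))
    # distance of (i, j) from each corner, counted in rows
    dist = {
        0: lambda i, j: i,              # top corner (0, 0)
        1: lambda i, j: (t - i) + j,    # bottom-left corner (t, 0)
        2: lambda i, j: t - j,          # bottom-right corner (t, t)
    }
    keep = {
        (i, j)
        for (i, j) in full
        if all(dist[c](i, j) >= rs[c] for c in range(3))
    }
    rot = _grid_rotation(keep, t)
    full_rot = _grid_rotation(full, t)
    ids = {v: k for k, v in enumerate(sorted(keep))}
    rotation = [tuple(ids[q] for q in rot[v]) for v in sorted(keep)]
    graph = PlanarEmbedding.from_rotation(rotation)
    reduced = {v for v in keep if len(rot[v]) < len(full_rot[v])}
    open_edges = tuple(
        sorted(
            (ids[u], ids[v])
            for u in reduced
            for v in rot[u]
            if v in reduced and ids[u] < ids[v]
        )
    )
    cut_rows = []
    for c in range(3):
        if rs[c] == 0:
            continue
        row = sorted(v for v in keep if dist[c](*v) == rs[c])
        cut_rows.append(tuple(ids[v] for v in row))
    return TriangleComponent(t, rs, graph, open_edges, tuple(cut_rows))


# --------------------------------------------------------------------------
# gSW-free family (four glued truncated triangles)
# --------------------------------------------------------------------------


def _glue_pieces(t: int, orientations: tuple[int, ...]) -> nx.Graph | None:
    """Glue four (2t,(t-1,t-1,t-1))-triangles tetrahedrally.

    Piece ``p``'s corners point at the other three labels in sorted order;
    the cut row of piece p towards q is identified with the cut row of piece
    q towards p (forward or reversed per ``orientations``).  Returns the
    glued graph on contracted vertices, or None if the result is not a
    planar triangulation with exactly four hexagonal faces.
    """
    piece = truncated_triangle(2 * t, t - 1, t - 1, t - 1)
    nv = piece.num_vertices
    g = nx.Graph()
    for p in range(4):
        off = p * nv
        g.add_nodes_from(off + v for v in range(nv))
        g.add_edges_from((off + u, off + v) for u, v in piece.graph.edges())
    # union-find for identifications
    parent = list(range(4 * nv))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    pairs = [(p, q) for p in range(4) for q in range(p + 1, 4)]
    for k, (p, q) in enumerate(pairs):
        cp = [o for o in range(4) if o != p].index(q)
        cq = [o for o in range(4) if o != q].index(p)
        row_p = [p * nv + v for v in piece.cut_rows[cp]]
        row_q = [q * nv + v for v in piece.cut_rows[cq]]
        if orientations[k]:
            row_q = row_q[::-1]
        for a, b in zip(row_p, row_q):
            union(a, b)
    mapping = {v: find(v) for v in g.nodes}
    glued = nx.relabel_nodes(g, mapping, copy=True)
    glued.remove_edges_from(nx.selfloop_edges(glued))
    glued = nx.convert_node_labels_to_integers(glued, ordering="sorted")
    if not nx.is_connected(glued):
        return None
    ok, _ = nx.check_planarity(glued)
    if not ok:
        return None
    try:
        emb = embedding_from_graph(glued)
    except ValidationError:
        return None
    sizes = sorted(len(f) for f in trace_faces(emb))
    if sizes.count(6) != 4 or sizes.count(3) != len(sizes) - 4:
        return None
    return glued


@lru_cache(maxsize=None)
def construction2(t: int) -> DualTriangulation:
    """Dual fullerene with ``n = 4(t^2+6t+7)`` vertices and no gSW path.

    Four ``(2t, (t-1, t-1, t-1))``-triangles are glued along their open cut
    rows in a tetrahedral pattern; the glued hexagonal graph has four
    hexagonal faces whose boundary degrees alternate 4 and 5, and a
    pentagonal 1-triangle is inserted into each of them.
    """
    if t < 2:
        raise ValidationError("construction needs t >= 2")
    glued = None
    for orientations in itertools.product((0, 1), repeat=6):
        glued = _glue_pieces(t, orientations)
        if glued is not None:
            break
    if glued is None:
        raise RuntimeError("no consistent gluing found")  # pragma: no cover
    emb = embedding_from_graph(glued)
    g = glued.copy()
    nxt = g.number_of_nodes()
    for face in trace_faces(emb):
        if len(face) != 6:
            continue
        b = list(face)
        if g.degree(b[0]) != 4:
            b = b[1:] + b[:1]
        if g.degree(b[0]) != 4:  # pragma: no cover
            raise RuntimeError("hexagonal face boundary does not alternate 4/5")
        pents = [nxt, nxt + 1, nxt + 2]
        nxt += 3
        for i in range(3):
            g.add_edge(pents[i], pents[(i + 1) % 3])
            for k in range(3):
                g.add_edge(pents[i], b[(2 * i + k) % 6])
    return DualTriangulation(embedding_from_graph(g)).validate()


def hexagonal_subgraph_counts(t: int) -> tuple[int, int, int]:
    """(hexagonal faces, triangular faces per piece, total vertices) of the
    glued hexagonal graph used by :func:`construction2`."""
    for orientations in itertools.product((0, 1), repeat=6):
        glued = _glue_pieces(t, orientations)
        if glued is not None:
            emb = embedding_from_graph(glued)
            sizes = [len(f) for f in trace_faces(emb)]
            return sizes.count(6), sizes.count(3), glued.number_of_nodes()
    raise RuntimeError("no consistent gluing found")  # pragma: no cover


# --------------------------------------------------------------------------
# seed fullerenes for isomerization algorithms (n >= 36)
# --------------------------------------------------------------------------

_SEED_PATTERN = (1, 2, 2, 2, 2, 3)


@lru_cache(maxsize=1)
def _seed_decomposition():
    """Split the dual of the first C36 isomer into cap + growable component.

    Searches for the unique (lexicographically first) connected cap ``B``
    whose removal leaves a connected component ``A`` bounded by a 6-cycle
    with degree-deficit labels (1,2,2,2,2,3); records the cyclic matching of
    the 12 cut edges so the cap can be sewn back onto any grown ``A``.
    """
    t36 = windup_dual(enumerate_codes(36)[0])
    g = t36.graph()
    m = t36.m
    best = None
    for size in range(3, m // 2 + 1):
        for b_nodes in itertools.combinations(range(m), size):
            bs = set(b_nodes)
            sub = g.subgraph(bs)
            if not nx.is_connected(sub):
                continue
            a_nodes = set(range(m)) - bs
            if not nx.is_connected(g.subgraph(a_nodes)):
                continue
            boundary = sorted(
                v for v in a_nodes if any(w in bs for w in g.neighbors(v))
            )
            if len(boundary) != 6:
                continue
            labels = {v: sum(1 for w in g.neighbors(v) if w in bs) for v in boundary}
            if sorted(labels.values()) != sorted(_SEED_PATTERN):
                continue
            # boundary must be a cycle in A
            asub = g.subgraph(a_nodes)
            if any(
                sum(1 for w in asub.neighbors(v) if w in boundary) != 2
                for v in boundary
            ):
                continue
            cyc = [boundary[0]]
            while len(cyc) < 6:
                nbrs = [
                    w
                    for w in asub.neighbors(cyc[-1])
                    if w in boundary and (len(cyc) < 2 or w != cyc[-2])
                    and w not in cyc
                ]
                if not nbrs:
                    break
                cyc.append(min(nbrs))
            if len(cyc) != 6 or cyc[0] not in asub.neighbors(cyc[-1]):
                continue
            seq = [labels[v] for v in cyc]
            ok_dir = None
            for d, s in ((1, seq), (-1, seq[::-1])):
                for shift in range(6):
                    if tuple(s[shift:] + s[:shift]) == _SEED_PATTERN:
                        ok_dir = (d, shift)
                        break
                if ok_dir:
                    break
            if ok_dir is None:
                continue
            d, shift = ok_dir
            oriented = cyc if d == 1 else cyc[::-1]
            oriented = oriented[shift:] + oriented[:shift]
            best = (bs, a_nodes, oriented, labels)
            break
        if best:
            break
    if best is None:  # pragma: no cover
        raise RuntimeError("no seed cap with boundary pattern (1,2,2,2,2,3)")
    bs, a_nodes, oriented, labels = best
    # cut-edge slots: walk the oriented boundary, repeating each vertex
    # `label` times; record which cap vertex each slot attaches to, using the
    # embedding's rotation to order multiple edges at one boundary vertex.
    rot = t36.embedding.rotation
    slots = []
    for idx, v in enumerate(oriented):
        nxt = oriented[(idx + 1) % 6]
        r = list(rot[v])
        k = r.index(nxt)
        ordered = r[k:] + r[:k]
        caps_here = [w for w in ordered if w in bs]
        if len(caps_here) != labels[v]:  # pragma: no cover
            raise RuntimeError("rotation order inconsistent with labels")
        slots.extend((v, w) for w in caps_here)
    a_graph = g.subgraph(a_nodes).copy()
    b_graph = g.subgraph(bs).copy()
    cap_slots = tuple(w for _, w in slots)
    return a_graph, b_graph, tuple(oriented), cap_slots, dict(labels)


def construction3(n: int) -> Fullerene:
    """A ``C_n`` seed isomer for any feasible ``n >= 36``.

    Starting from the decomposition of the first C36 isomer, the growable
    component's boundary (label vector (1,2,2,2,2,3), labels ``6 - deg``) is
    extended ``n/2 - 18`` times by attaching one new dual vertex to the
    label-1 vertex and its boundary neighbours labelled 2 and 3; the cap is
    then sewn back along the preserved cut pattern.
    """
    if n < 36 or n % 2:
        raise ValidationError("construction needs even n >= 36")
    a_graph, b_graph, boundary, cap_slots, labels0 = _seed_decomposition()
    a = a_graph.copy()
    cycle = list(boundary)  # ordered so labels read (1,2,2,2,2,3)
    labels = [labels0[v] for v in cycle]
    assert tuple(labels) == _SEED_PATTERN
    new_id = max(max(a.nodes), max(b_graph.nodes)) + 1
    for _ in range(n // 2 - 18):
        v1 = cycle[0]
        v2 = cycle[1]       # label 2 neighbour
        v3 = cycle[-1]      # label 3 neighbour
        u = new_id
        new_id += 1
        a.add_edges_from([(u, v1), (u, v2), (u, v3)])
        cycle = [v2, *cycle[2:-1], v3, u]
        # labels: v2 2->1, v3 3->2, u has degree 3 -> label 3
    out = nx.union(a, b_graph)
    slots_a = []
    for idx, v in enumerate(cycle):
        lab = _SEED_PATTERN[idx]
        slots_a.extend([v] * lab)
    for va, vb in zip(slots_a, cap_slots):
        out.add_edge(va, vb)
    out = nx.convert_node_labels_to_integers(out, ordering="sorted")
    t = DualTriangulation(embedding_from_graph(out)).validate()
    return dualize_inverse(t)


# --------------------------------------------------------------------------
# nanotubes, Goldberg polyhedra, prism duals
# --------------------------------------------------------------------------


def nanotube_5_0(n: int) -> Fullerene:
    """(5,0)-nanotube: two 6-pentagon caps separated by (n-20)/10 belts.

    The dual has two apex-and-ring caps of six degree-5 vertices and
    ``r = (n - 20)/10`` five-vertex hexagonal belts; for n = 20 it degenerates
    to the icosahedron (dodecahedral fullerene).
    """
    if n < 20 or n % 10:
        raise ValidationError(f"(5,0)-nanotube needs n = 20 + 10r, got {n}")
    r = (n - 20) // 10
    g = nx.Graph()
    rings = r + 2
    ring = lambda i, k: 1 + 5 * i + (k % 5)  # noqa: E731
    apex0, apex1 = 0, 5 * rings + 1
    for k in range(5):
        g.add_edge(apex0, ring(0, k))
        g.add_edge(apex1, ring(rings - 1, k))
    for i in range(rings):
        for k in range(5):
            g.add_edge(ring(i, k), ring(i, k + 1))
    for i in range(rings - 1):
        for k in range(5):
            g.add_edge(ring(i + 1, k), ring(i, k))
            g.add_edge(ring(i + 1, k), ring(i, k + 1))
    t = DualTriangulation(embedding_from_graph(g)).validate()
    return dualize_inverse(t)


_PHI = (1 + 5**0.5) / 2
_ICO_COORDS = np.array(
    [
        (0, s1, s2 * _PHI)[k:] + (0, s1, s2 * _PHI)[:k]
        for k in range(3)
        for s1 in (-1, 1)
        for s2 in (-1, 1)
    ],
    dtype=float,
)


def goldberg(p: int, q: int) -> Fullerene:
    """Goldberg polyhedron ``G(p, q)``: icosahedral fullerene,
    ``n = 20(p^2 + pq + q^2)``.

    Built by Goldberg-Coxeter subdivision: each icosahedron face carries the
    triangular-lattice triangle with corners 0, ``p + q*omega`` and its
    60-degree rotation; lattice points are mapped barycentrically onto the
    face and projected to the sphere, and the dual triangulation is read off
    the convex hull.  IPR for every n > 20.
    """
    if q < 0 or p < q or p < 1:
        raise ValidationError(f"need p >= q >= 0 and p >= 1, got ({p}, {q})")
    omega = np.exp(1j * np.pi / 3)
    z1 = p + q * omega
    z2 = z1 * omega
    # lattice points inside the master triangle (0, z1, z2)
    span = p + q + 1
    mat = np.array([[z1.real, z2.real], [z1.imag, z2.imag]])
    inv = np.linalg.inv(mat)
    pts = []
    hull0 = ConvexHull(_ICO_COORDS)
    for simplex in hull0.simplices:
        a, b, c = (_ICO_COORDS[k] for k in simplex)
        if np.dot(np.cross(b - a, c - a), a + b + c) < 0:
            b, c = c, b
        for u in range(-span, span + 1):
            for v in range(-span, span + 1):
                z = u + v * omega
                s, t = inv @ (z.real, z.imag)
                if s < -1e-9 or t < -1e-9 or s + t > 1 + 1e-9:
                    continue
                pts.append(a + s * (b - a) + t * (c - a))
    pts = np.array(pts)
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    _, idx = np.unique(np.round(pts, 6), axis=0, return_index=True)
    pts = pts[sorted(idx)]
    hull = ConvexHull(pts)
    g = nx.Graph()
    for tri in hull.simplices:
        g.add_edges_from(
            [(int(tri[0]), int(tri[1])), (int(tri[1]), int(tri[2])),
             (int(tri[0]), int(tri[2]))]
        )
    t = DualTriangulation(embedding_from_graph(g)).validate()
    expected = 20 * (p * p + p * q + q * q)
    if t.n != expected:  # pragma: no cover
        raise RuntimeError(f"Goldberg({p},{q}) produced n={t.n}, expected {expected}")
    return dualize_inverse(t)


def chamfer(t: DualTriangulation) -> DualTriangulation:
    """Goldberg-Coxeter (2,0) subdivision of a dual triangulation.

    Every triangle is split into four through the edge midpoints; original
    vertices keep their degree and every midpoint has degree 6, so the dual
    of a ``C_n`` fullerene maps to the dual of a ``C_{4n}`` one (the chamfer
    of the fullerene).  chamfer of the icosahedron = Goldberg(2, 0).
    """
    g = nx.Graph()
    mid: dict[tuple[int, int], int] = {}
    nxt = t.m
    for u, v in t.embedding.edges():
        mid[(u, v)] = mid[(v, u)] = nxt
        nxt += 1
    for face in trace_faces(t.embedding):
        a, b, c = face
        mab, mbc, mca = mid[(a, b)], mid[(b, c)], mid[(c, a)]
        g.add_edges_from(
            [
                (a, mab), (a, mca), (mab, mca),
                (b, mab), (b, mbc), (mab, mbc),
                (c, mbc), (c, mca), (mbc, mca),
            ]
        )
    return DualTriangulation(embedding_from_graph(g)).validate()


def bipyramid_seed(m: int) -> PlanarEmbedding:
    """Dual of the (m-2)-gonal prism: the classical seed for flip walks.

    Two apices of degree ``m - 2`` over a ring of degree-4 vertices; it has
    the vertex/edge/face counts of a dual fullerene of ``C_{2(m-2)}`` but is
    (for m > 12) not one.
    """
    if m < 5:
        raise ValidationError("need m >= 5")
    g = nx.Graph()
    ring = m - 2
    for k in range(ring):
        g.add_edge(k, (k + 1) % ring)
        g.add_edge(ring, k)
        g.add_edge(ring + 1, k)
    return embedding_from_graph(g)
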