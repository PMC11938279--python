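"""Stone-Wales family of isomerization operations on dual triangulations.

All operations act on the dual side, where the classic Stone-Wales rotation
of a pentagon-hexagon-pentagon-hexagon patch becomes a single diagonal edge
flip.  Three flavours are provided:

* ``psw_flip`` -- the polyhedral Stone-Wales operation: one diagonal flip on
  any triangulation edge.  Complete (by Wagner's theorem any two sphere
  triangulations of equal size are flip-connected) but not closed on
  fullerenes, since it changes vertex degrees.
* ``apply_gsw`` -- the generalized Stone-Wales operation: transports a
  pentagonal defect along a zigzag *gSW path* by a cascade of diagonal
  flips.  Closed on fullerenes and self-inverse.
* ``psw_random_walk`` -- uniform random flips, flagging dual-fullerene
  states along the way.

A gSW path ``(v_1, ..., v_2w)``, ``w >= 2``, requires: deg(v_1) = deg(v_2w)
= 5, deg(v_2) = deg(v_{2w-1}) = 6, all vertices distinct, consecutive
vertices adjacent and every skip pair ``(v_i, v_{i+2})`` adjacent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import PlanarEmbedding, ValidationError, trace_faces
from .fullerene import DualTriangulation

__all__ = [
    "GswPath",
    "FlipError",
    "psw_flip",
    "find_gsw_paths",
    "has_gsw_path",
    "apply_gsw",
    "transformed_path",
    "psw_random_walk",
    "is_dual_fullerene",
]


class FlipError(ValidationError):
    """A requested flip violates its precondition."""


@dataclass(frozen=True)
class GswPath:
    """Zigzag vertex sequence ``(v_1, ..., v_2w)`` satisfying the gSW rules."""

    vertices: tuple[int, ...]

    @property
    def w(self) -> int:
        return len(self.vertices) // 2

    def validate_in(self, t: DualTriangulation) -> "GswPath":
        v = self.vertices
        if len(v) < 4 or len(v) % 2:
            raise ValidationError(f"gSW path needs even length >= 4: {v}")
        if len(set(v)) != len(v):
            raise ValidationError("gSW path vertices must be distinct")
        adj = t.adjacency
        deg = t.embedding.degrees()
        if deg[v[0]] != 5 or deg[v[-1]] != 5:
            raise ValidationError("gSW path must start and end at degree-5 vertices")
        if deg[v[1]] != 6 or deg[v[-2]] != 6:
            raise ValidationError(
                "second and penultimate gSW path vertices must have degree 6"
            )
        for i in range(len(v) - 1):
            if v[i + 1] not in adj[v[i]]:
                raise ValidationError(f"({v[i]}, {v[i+1]}) is not an edge")
        for i in range(len(v) - 2):
            if v[i + 2] not in adj[v[i]]:
                raise ValidationError(f"skip pair ({v[i]}, {v[i+2]}) is not an edge")
        return self


def _flip_rotation(rotation: list[list[int]], a: int, b: int) -> tuple[int, int]:
    """Diagonal-flip edge (a, b) in a triangulation rotation system, in place.

    Returns the new edge (c, d).  The two triangles on (a, b) are (a, b, c)
    and (a, b, d); the flip removes (a, b) and inserts (c, d), splicing d into
    the rotation of c between its (cyclically adjacent) neighbours a and b,
    and vice versa.
    """
    if b not in rotation[a]:
        raise FlipError(f"({a}, {b}) is not an edge")
    # apexes of the two triangular faces at (a, b), read off the rotation
    # (graph-common neighbours are not reliable on dense small graphs)
    rot_a = rotation[a]
    ib = rot_a.index(b)
    c = rot_a[(ib + 1) % len(rot_a)]
    d = rot_a[ib - 1]
    if c == d:
        raise FlipError(f"edge ({a}, {b}) lies on a single triangle")
    if d in rotation[c]:
        raise FlipError(
            f"flip of ({a}, {b}) would duplicate existing edge ({c}, {d})"
        )
    if len(rotation[a]) <= 3 or len(rotation[b]) <= 3:
        raise FlipError(f"flip of ({a}, {b}) would create a degree-2 vertex")
    for x, y in ((c, d), (d, c)):
        rot = rotation[x]
        ia = rot.index(a)
        ib = rot.index(b)
        n = len(rot)
        if (ia + 1) % n == ib:
            rot.insert(ib, y)
        elif (ib + 1) % n == ia:
            rot.insert(ia, y)
        else:
            raise FlipError(
                f"vertices a={a}, b={b} are not consecutive around {x}"
            )
    rotation[a].remove(b)
    rotation[b].remove(a)
    return c, d


def psw_flip(t: DualTriangulation | PlanarEmbedding, edge) -> PlanarEmbedding:
    """Polyhedral Stone-Wales flip of one edge of a sphere triangulation.

    Removes ``edge = (v1, v2)`` and joins the two common neighbours of its
    endpoints.  The result is again a sphere triangulation on the same vertex
    set (generally not a dual fullerene: the four involved degrees change by
    one).  Flipping the new edge back restores the input.
    """
    emb = t.embedding if isinstance(t, DualTriangulation) else t
    a, b = edge
    rotation = [list(nbrs) for nbrs in emb.rotation]
    _flip_rotation(rotation, a, b)
    out = PlanarEmbedding.from_rotation(rotation)
    if any(len(f) != 3 for f in trace_faces(out)):
        raise FlipError("flip produced a non-triangular face")  # pragma: no cover
    return out


def is_dual_fullerene(emb: PlanarEmbedding) -> bool:
    """True iff a triangulation embedding satisfies the dual-fullerene census."""
    degs = emb.degrees()
    if any(d not in (5, 6) for d in degs) or degs.count(5) != 12:
        return False
    return all(len(f) == 3 for f in trace_faces(emb))


def find_gsw_paths(
    t,
    max_w: int | None = None,
    first_only: bool = False,
    hex_interior: bool = False,
) -> list[GswPath]:
    """All gSW paths of ``t`` with ``2 <= w <= max_w``, by zigzag DFS.

    The skip-adjacency rule leaves at most two extension candidates per step
    (the two common neighbours of the last two vertices), so the search is a
    shallow branching walk from every (degree-5, degree-6) start edge.
    Output is sorted lexicographically by vertex sequence.  ``t`` may be a
    :class:`DualTriangulation` or a plain adjacency-set list.
    """
    if isinstance(t, DualTriangulation):
        adj = t.adjacency
        deg = t.embedding.degrees()
        m = t.m
    else:
        adj = t
        deg = [len(s) for s in adj]
        m = len(adj)
    if max_w is None:
        max_w = m // 2
    out: list[tuple[int, ...]] = []

    def extend(path: list[int], in_path: set[int]):
        k = len(path)
        if k >= 4 and k % 2 == 0 and deg[path[-1]] == 5 and deg[path[-2]] == 6:
            # hex_interior: the defect-transport reading where all interior
            # vertices v_3..v_{2w-2} stay in the hexagonal subgraph
            if not hex_interior or all(deg[x] == 6 for x in path[2:-2]):
                out.append(tuple(path))
                if first_only:
                    raise StopIteration
        if k >= 2 * max_w:
            return
        # next vertex must be adjacent to the last vertex and (skip rule)
        # to the one before it
        for x in sorted(adj[path[-1]] & adj[path[-2]]):
            if x not in in_path:
                if hex_interior and k >= 3 and deg[path[-1]] != 6:
                    # interior vertices must stay hexagonal once past v_2
                    continue
                path.append(x)
                in_path.add(x)
                extend(path, in_path)
                path.pop()
                in_path.remove(x)

    try:
        for v1 in range(m):
            if deg[v1] != 5:
                continue
            for v2 in sorted(adj[v1]):
                if deg[v2] != 6:
                    continue
                extend([v1, v2], {v1, v2})
    except StopIteration:
        pass
    return [GswPath(p) for p in sorted(out)]


def has_gsw_path(t, max_w: int | None = None, hex_interior: bool = False) -> bool:
    """True iff the gSW operation is applicable to this fullerene."""
    return bool(
        find_gsw_paths(t, max_w=max_w, first_only=True, hex_interior=hex_interior)
    )


def apply_gsw(t: DualTriangulation, p: GswPath) -> DualTriangulation:
    """Apply the generalized Stone-Wales operation along path ``p``.

    Implemented as the cascade of ``w - 1`` diagonal flips that removes the
    edges ``(v_2k, v_2k+1)`` and inserts ``(v_2k-1, v_2k+2)``; the pentagonal
    ends trade degrees with their hexagonal neighbours
    (deg v_1: 5->6, v_2: 6->5, v_{2w-1}: 6->5, v_2w: 5->6) while every
    intermediate degree is preserved, so the result is again a dual
    fullerene.  The reversed-pairs sequence ``(v_2, v_1, v_4, v_3, ...)``
    forms a gSW path of the output, along which a second application undoes
    the first.
    """
    p.validate_in(t)
    v = p.vertices
    rotation = [list(nbrs) for nbrs in t.embedding.rotation]
    for k in range(0, len(v) - 2, 2):
        a, b = v[k + 1], v[k + 2]
        c, d = _flip_rotation(rotation, a, b)
        if {c, d} != {v[k], v[k + 3]}:  # pragma: no cover - guarded by validate
            raise FlipError(
                f"flip of ({a}, {b}) produced ({c}, {d}), expected "
                f"({v[k]}, {v[k+3]})"
            )
    out = DualTriangulation(PlanarEmbedding.from_rotation(rotation))
    return out.validate()


def transformed_path(p: GswPath) -> GswPath:
    """The image path ``(v_2, v_1, v_4, v_3, ...)`` along which gSW inverts."""
    v = p.vertices
    sw = []
    for k in range(0, len(v), 2):
        sw.extend((v[k + 1], v[k]))
    return GswPath(tuple(sw))


def psw_random_walk(
    t: PlanarEmbedding | DualTriangulation, steps: int, rng_seed: int
) -> list[tuple[PlanarEmbedding, bool]]:
    """Uniform random pSW flips on a sphere triangulation.

    Returns the trajectory ``[(state, is_dual_fullerene), ...]`` of length
    ``steps + 1`` including the seed state.  Non-flippable edges (those whose
    flip would duplicate an edge or create a degree-2 vertex) are excluded
    from the draw at each step; reproducible from ``rng_seed``.
    """
    emb = t.embedding if isinstance(t, DualTriangulation) else t
    rng = np.random.default_rng(rng_seed)
    trace = [(emb, is_dual_fullerene(emb))]
    for _ in range(steps):
        edges = emb.edges()
        flippable = []
        for e in edges:
            rotation = [list(nbrs) for nbrs in emb.rotation]
            try:
                _flip_rotation(rotation, *e)
            except FlipError:
                continue
            flippable.append((e, rotation))
        if not flippable:  # cannot occur for m >= 5; guard anyway
            break
        _, rotation = flippable[rng.integers(len(flippable))]
        emb = PlanarEmbedding.from_rotation(rotation)
        trace.append((emb, is_dual_fullerene(emb)))
    return trace
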