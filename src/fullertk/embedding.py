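"""Rotation-system representation of planar graphs.

A combinatorial (genus-0) embedding of a connected simple graph is given by a
*rotation system*: for every vertex, the cyclic counterclockwise order of its
neighbours.  Faces are recovered by dart tracing, the dual embedding by
replacing faces with vertices.  All vertex ids are 0-based contiguous
integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "EmbeddingError",
    "ValidationError",
    "PlanarEmbedding",
    "trace_faces",
    "dual_embedding",
    "embedding_from_graph",
]


class ValidationError(ValueError):
    """An object violates its structural invariants."""


class EmbeddingError(ValidationError):
    """A rotation system does not describe a sphere embedding."""


@dataclass(frozen=True)
class PlanarEmbedding:
    """A connected simple graph with a genus-0 rotation system.

    Parameters
    ----------
    rotation:
        ``rotation[v]`` is the tuple of neighbours of ``v`` in counterclockwise
        cyclic order.  Vertex ids are ``0 .. len(rotation)-1``.
    """

    rotation: tuple[tuple[int, ...], ...]

    @property
    def num_vertices(self) -> int:
        return len(self.rotation)

    @property
    def num_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.rotation) // 2

    def degree(self, v: int) -> int:
        return len(self.rotation[v])

    def degrees(self) -> list[int]:
        return [len(nbrs) for nbrs in self.rotation]

    def edges(self) -> list[tuple[int, int]]:
        return [
            (u, v) for u, nbrs in enumerate(self.rotation) for v in nbrs if u < v
        ]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.num_vertices))
        g.add_edges_from(self.edges())
        return g

    @staticmethod
    def from_rotation(rotation: Sequence[Sequence[int]]) -> "PlanarEmbedding":
        emb = PlanarEmbedding(tuple(tuple(nbrs) for nbrs in rotation))
        emb.validate()
        return emb

    def validate(self) -> None:
        n = self.num_vertices
        if n < 1:
            raise ValidationError("empty vertex set")
        seen: set[tuple[int, int]] = set()
        for u, nbrs in enumerate(self.rotation):
            for v in nbrs:
                if not 0 <= v < n:
                    raise ValidationError(f"vertex {u} lists unknown neighbour {v}")
                if v == u:
                    raise ValidationError(f"loop at vertex {u}")
                if (u, v) in seen:
                    raise ValidationError(f"parallel edge ({u}, {v})")
                seen.add((u, v))
        for u, v in seen:
            if (v, u) not in seen:
                raise ValidationError(f"edge ({u}, {v}) missing its reverse")
        if n > 1 and not _connected(self.rotation):
            raise ValidationError("graph is not connected")
        # Euler genus check: raises EmbeddingError if the face count is wrong.
        trace_faces(self)


def _connected(rotation: Sequence[Sequence[int]]) -> bool:
    n = len(rotation)
    seen = [False] * n
    stack = [0]
    seen[0] = True
    count = 1
    while stack:
        u = stack.pop()
        for v in rotation[u]:
            if not seen[v]:
                seen[v] = True
                count += 1
                stack.append(v)
    return count == n


def trace_faces(emb: PlanarEmbedding) -> list[tuple[int, ...]]:
    """Trace the faces of a rotation system.

    Faces are orbits of darts under the rule: after arriving along ``u -> v``,
    leave through the edge clockwise-next after ``(v, u)`` in the rotation of
    ``v`` (i.e. the predecessor of ``u`` in the counterclockwise order).  Every
    directed edge lies on exactly one face walk.  Raises
    :class:`EmbeddingError` when Euler's relation ``V - E + F = 2`` fails.
    """
    rotation = emb.rotation
    if emb.num_vertices == 1 and not rotation[0]:
        return [()]  # single vertex on the sphere: one (empty-walk) face
    index = [
        {v: i for i, v in enumerate(nbrs)} for nbrs in rotation
    ]
    unused: set[tuple[int, int]] = {
        (u, v) for u, nbrs in enumerate(rotation) for v in nbrs
    }
    faces: list[tuple[int, ...]] = []
    while unused:
        start = min(unused)
        walk = []
        dart = start
        while True:
            walk.append(dart[0])
            unused.discard(dart)
            u, v = dart
            nbrs = rotation[v]
            i = index[v][u]
            dart = (v, nbrs[i - 1])
            if dart == start:
                break
            if dart not in unused:
                raise EmbeddingError("face tracing revisited a dart")
        faces.append(tuple(walk))
    n_edges = emb.num_edges
    if emb.num_vertices - n_edges + len(faces) != 2:
        raise EmbeddingError(
            f"rotation system has genus > 0: V={emb.num_vertices} "
            f"E={n_edges} F={len(faces)}"
        )
    return faces


def dual_embedding(emb: PlanarEmbedding) -> PlanarEmbedding:
    """Geometric dual of a sphere embedding, with the induced rotation system.

    Faces become vertices; two dual vertices are adjacent when the faces share
    an edge.  The rotation of a dual vertex lists the faces met while walking
    around the primal face.  Applying the operation twice returns a graph
    isomorphic to the input (this is the standard dual of a 3-connected
    polyhedral embedding; no face may share more than one edge with another).
    """
    faces = trace_faces(emb)
    face_of_dart: dict[tuple[int, int], int] = {}
    for fi, walk in enumerate(faces):
        for k, u in enumerate(walk):
            v = walk[(k + 1) % len(walk)]
            face_of_dart[(u, v)] = fi
    rotation = []
    for fi, walk in enumerate(faces):
        nbrs = []
        for k, u in enumerate(walk):
            v = walk[(k + 1) % len(walk)]
            other = face_of_dart[(v, u)]
            if other == fi:
                raise ValidationError("dual would contain a loop (bridge edge)")
            nbrs.append(other)
        if len(set(nbrs)) != len(nbrs):
            raise ValidationError(
                "dual would contain parallel edges; embedding is not polyhedral"
            )
        rotation.append(tuple(nbrs))
    return PlanarEmbedding.from_rotation(rotation)


def embedding_from_graph(g: nx.Graph) -> PlanarEmbedding:
    """Compute a rotation system for a planar ``networkx`` graph.

    The graph must be planar and connected; for 3-connected graphs the
    embedding is unique up to reflection, so downstream canonical codes (which
    scan both winding directions) do not depend on the choice.  Nodes must be
    0-based contiguous integers.
    """
    n = g.number_of_nodes()
    if sorted(g.nodes) != list(range(n)):
        raise ValidationError("nodes must be 0..n-1 integers")
    ok, pemb = nx.check_planarity(g)
    if not ok:
        raise EmbeddingError("graph is not planar")
    rotation = []
    for v in range(n):
        nbrs = list(pemb.neighbors_cw_order(v)) if g.degree(v) else []
        # networkx reports clockwise order; store counterclockwise.
        rotation.append(tuple(reversed(nbrs)))
    return PlanarEmbedding.from_rotation(rotation)
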