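"""Fullerene graphs and their dual triangulations.

A fullerene on ``n`` vertices is a 3-regular sphere embedding whose faces are
12 pentagons and ``n/2 - 10`` hexagons; its dual ``T_n`` is a sphere
triangulation on ``m = n/2 + 2`` vertices with degrees in {5, 6}, exactly
twelve of degree 5.  The subgraph of ``T_n`` induced by the degree-5 vertices
(``T_n^5``) encodes the pentagon clusters; the degree-6 part (``T_n^6``)
encodes hexagon connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import networkx as nx

from .embedding import (
    PlanarEmbedding,
    ValidationError,
    dual_embedding,
    embedding_from_graph,
    trace_faces,
)

__all__ = [
    "Fullerene",
    "DualTriangulation",
    "PentagonPartition",
    "dualize",
    "dualize_inverse",
    "subgraph5",
    "subgraph6",
    "pentagon_partition",
    "is_ipr",
    "count_integer_partitions",
    "is_feasible",
]


def is_feasible(n: int) -> bool:
    """True iff some fullerene with ``n`` vertices exists."""
    return n >= 20 and n % 2 == 0 and n != 22


@dataclass(frozen=True)
class Fullerene:
    """A 3-regular sphere embedding with pentagonal/hexagonal faces only."""

    embedding: PlanarEmbedding

    @property
    def n(self) -> int:
        return self.embedding.num_vertices

    def validate(self) -> "Fullerene":
        self.embedding.validate()
        n = self.n
        if not is_feasible(n):
            raise ValidationError(f"infeasible vertex count n={n}")
        if any(d != 3 for d in self.embedding.degrees()):
            raise ValidationError("fullerene must be 3-regular")
        sizes = sorted(len(f) for f in trace_faces(self.embedding))
        pentagons = sizes.count(5)
        hexagons = sizes.count(6)
        if pentagons != 12 or hexagons != n // 2 - 10 or len(sizes) != n // 2 + 2:
            raise ValidationError(
                f"face census {sizes} is not 12 pentagons + {n // 2 - 10} hexagons"
            )
        return self


@dataclass(frozen=True)
class DualTriangulation:
    """Sphere triangulation with degrees in {5, 6}, twelve of degree 5 (T_n)."""

    embedding: PlanarEmbedding

    @property
    def m(self) -> int:
        return self.embedding.num_vertices

    @property
    def n(self) -> int:
        """Vertex count of the primal fullerene (m = n/2 + 2)."""
        return 2 * (self.m - 2)

    @cached_property
    def adjacency(self) -> tuple[frozenset, ...]:
        return tuple(frozenset(nbrs) for nbrs in self.embedding.rotation)

    def graph(self) -> nx.Graph:
        return self.embedding.to_networkx()

    def validate(self) -> "DualTriangulation":
        self.embedding.validate()
        degs = self.embedding.degrees()
        if any(d not in (5, 6) for d in degs):
            raise ValidationError("dual fullerene degrees must be 5 or 6")
        if degs.count(5) != 12:
            raise ValidationError(
                f"dual fullerene needs exactly 12 degree-5 vertices, got {degs.count(5)}"
            )
        if any(len(f) != 3 for f in trace_faces(self.embedding)):
            raise ValidationError("all faces must be triangles")
        return self


@dataclass(frozen=True)
class PentagonPartition:
    """Sizes of the pentagon clusters: a partition of 12."""

    parts: tuple[int, ...]

    def __post_init__(self):
        if sum(self.parts) != 12 or any(p < 1 for p in self.parts):
            raise ValidationError(f"not a partition of 12: {self.parts}")
        if list(self.parts) != sorted(self.parts, reverse=True):
            raise ValidationError("parts must be non-increasing")


def dualize(f: Fullerene) -> DualTriangulation:
    """Dual triangulation of a fullerene (unique by 3-connectivity)."""
    return DualTriangulation(dual_embedding(f.embedding)).validate()


def dualize_inverse(t: DualTriangulation) -> Fullerene:
    """Fullerene whose dual is ``t`` (dualization applied to the dual)."""
    return Fullerene(dual_embedding(t.embedding)).validate()


def _induced(t: DualTriangulation, keep_degree: int) -> nx.Graph:
    degs = t.embedding.degrees()
    keep = [v for v in range(t.m) if degs[v] == keep_degree]
    return t.graph().subgraph(keep).copy()


def subgraph5(t: DualTriangulation) -> nx.Graph:
    """T_n^5: subgraph induced by the 12 degree-5 (pentagonal) vertices."""
    return _induced(t, 5)


def subgraph6(t: DualTriangulation) -> nx.Graph:
    """T_n^6: subgraph induced by the n/2 - 10 degree-6 (hexagonal) vertices."""
    return _induced(t, 6)


def pentagon_partition(t: DualTriangulation) -> PentagonPartition:
    """Connected-component sizes of T_n^5, sorted non-increasingly."""
    comps = nx.connected_components(subgraph5(t))
    parts = tuple(sorted((len(c) for c in comps), reverse=True))
    return PentagonPartition(parts)


def is_ipr(t: DualTriangulation) -> bool:
    """Isolated Pentagon Rule: no two degree-5 vertices adjacent."""
    return subgraph5(t).number_of_edges() == 0


def count_integer_partitions(k: int) -> int:
    """Number of integer partitions of ``k`` (Euler's recurrence by DP)."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    table = [1] + [0] * k
    for part in range(1, k + 1):
        for total in range(part, k + 1):
            table[total] += table[total - part]
    return table[k]
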