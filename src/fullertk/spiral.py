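"""Face-spiral codes: windup, canonical unwind, enumeration and sampling.

A fullerene is peeled face by face in a tight spiral; recording pentagon (5)
versus hexagon (6) gives a size sequence of length ``m = n/2 + 2``, compactly
stored as the 12 positions of the pentagons (1-based).  The canonical code of
an isomer is the lexicographically smallest successful spiral over all start
faces and both winding directions; listing canonical codes in ascending
pentagon-position order enumerates the isomer classes ``C_{n,1} ..
C_{n,iso(n)}``.

The acceptance-rejection sampler draws uniform pentagon-position vectors and
keeps exactly those equal to the canonical code of the fullerene they wind
into, which makes the accepted isomer uniform on ``C_n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

import networkx as nx
import numpy as np

from . import _spiralkernels as _k
from .embedding import ValidationError, embedding_from_graph
from .fullerene import DualTriangulation, Fullerene, dualize, dualize_inverse, is_feasible

__all__ = [
    "SpiralCode",
    "IsomerIndex",
    "SpiralRejection",
    "NoSpiralError",
    "windup",
    "windup_dual",
    "unwind_canonical",
    "canonical_code",
    "enumerate_isomers",
    "enumerate_codes",
    "isomer_count",
    "isomer_by_index",
    "last_isomer",
    "unrank_pentagon_vector",
    "rank_pentagon_vector",
    "sample_rejection",
    "sample_many",
    "acceptance_rate",
]


class SpiralRejection(Exception):
    """A well-formed spiral code that does not close into a fullerene."""


class NoSpiralError(ValidationError):
    """No face spiral exists for the given fullerene.

    The smallest fullerenes without any successful spiral have n = 380, far
    beyond this package's enumeration range, but the condition is reported
    explicitly rather than silently mis-encoded.
    """


@dataclass(frozen=True, order=True)
class SpiralCode:
    """Face-size sequence of a spiral, stored as 12 pentagon positions."""

    n: int
    pentagon_positions: tuple[int, ...]

    def __post_init__(self):
        m = self.m
        pp = self.pentagon_positions
        if len(pp) != 12:
            raise ValidationError(f"need 12 pentagon positions, got {len(pp)}")
        if list(pp) != sorted(set(pp)) or pp[0] < 1 or pp[-1] > m:
            raise ValidationError(
                f"positions must be strictly increasing within 1..{m}: {pp}"
            )

    @property
    def m(self) -> int:
        return self.n // 2 + 2

    @property
    def sizes(self) -> tuple[int, ...]:
        pent = set(self.pentagon_positions)
        return tuple(5 if i + 1 in pent else 6 for i in range(self.m))

    @staticmethod
    def from_sizes(sizes) -> "SpiralCode":
        sizes = tuple(sizes)
        n = 2 * (len(sizes) - 2)
        pp = tuple(i + 1 for i, s in enumerate(sizes) if s == 5)
        return SpiralCode(n, pp)


@dataclass(frozen=True)
class IsomerIndex:
    """``C_{n,j}``: the j-th isomer in pentagon-position lexicographic order."""

    n: int
    j: int


def _dual_from_adjsets(adjsets) -> DualTriangulation:
    g = nx.Graph()
    g.add_nodes_from(range(len(adjsets)))
    for u, nbrs in enumerate(adjsets):
        for v in nbrs:
            if u < v:
                g.add_edge(u, v)
    return DualTriangulation(embedding_from_graph(g)).validate()


def windup_adjacency(code: SpiralCode) -> list[set]:
    """Adjacency sets of the dual triangulation, without an embedding.

    Cheaper than :func:`windup_dual` for bulk scans that only need the
    abstract graph (degree census, gSW path search, spectra).
    """
    adj = _k.windup_adj_py(code.sizes)
    if adj is None:
        raise SpiralRejection(f"spiral does not close: {code}")
    return adj


def windup_dual(code: SpiralCode) -> DualTriangulation:
    """Wind a spiral code into its dual triangulation.

    Raises :class:`SpiralRejection` when the spiral does not close (this is a
    result, not a malformed input).
    """
    adj = _k.windup_adj_py(code.sizes)
    if adj is None:
        raise SpiralRejection(f"spiral does not close: {code}")
    return _dual_from_adjsets(adj)


def windup(code: SpiralCode) -> Fullerene:
    """Wind a spiral code into a fullerene graph."""
    return dualize_inverse(windup_dual(code))


def canonical_code(t: DualTriangulation) -> SpiralCode:
    """Canonical (lex-min) spiral code of a dual triangulation."""
    adj = [set(s) for s in t.adjacency]
    degs = [len(s) for s in adj]
    seq = _k.canonical_code_py(adj, degs)
    if seq is None:
        raise NoSpiralError(
            f"no face spiral exists for this fullerene (m={t.m})"
        )
    return SpiralCode.from_sizes(seq)


def unwind_canonical(f: Fullerene) -> SpiralCode:
    """Canonical spiral code of a fullerene (isomorphism invariant)."""
    return canonical_code(dualize(f))


@lru_cache(maxsize=None)
def enumerate_codes(n: int) -> tuple[SpiralCode, ...]:
    """All canonical spiral codes with ``n`` vertices, ascending.

    Backtracking windup search over partial spirals with early rejection; each
    completed spiral is emitted iff it is its own canonical form.
    """
    if n < 20 or n % 2:
        raise ValidationError(f"n must be even and >= 20, got {n}")
    m = n // 2 + 2
    rows, cnt, _stats = _k._enumerate_kernel(m, False, -1)
    return tuple(SpiralCode(n, tuple(int(x) for x in rows[i])) for i in range(cnt))


def enumerate_isomers(n: int) -> Iterator[SpiralCode]:
    """Stream the canonical codes of all ``C_n`` isomers in lexicographic order."""
    yield from enumerate_codes(n)


def isomer_count(n: int) -> int:
    """iso(n): the number of isomorphism classes of fullerenes on n vertices."""
    return len(enumerate_codes(n))


def isomer_by_index(idx: IsomerIndex | tuple[int, int]) -> Fullerene:
    """``C_{n,j}`` as a fullerene graph (1-based lexicographic rank ``j``)."""
    if isinstance(idx, tuple):
        idx = IsomerIndex(*idx)
    codes = enumerate_codes(idx.n)
    if not 1 <= idx.j <= len(codes):
        raise ValidationError(
            f"isomer index {idx.j} out of range 1..{len(codes)} for n={idx.n}"
        )
    return windup(codes[idx.j - 1])


def last_isomer_code(n: int) -> SpiralCode:
    """Lexicographically largest canonical code in ``C_n``.

    Found by reverse-order backtracking (first hit), avoiding a full
    enumeration; used for the large gSW counterexamples.
    """
    m = n // 2 + 2
    rows, cnt, _stats = _k._enumerate_kernel(m, True, 1)
    if cnt == 0:
        raise ValidationError(f"no isomers for n={n}")
    return SpiralCode(n, tuple(int(x) for x in rows[0]))


def last_isomer(n: int) -> Fullerene:
    return windup(last_isomer_code(n))


def unrank_pentagon_vector(N: int, length: int) -> tuple[int, ...]:
    """N-th 12-subset of {1..length} in lexicographic order (1-based N)."""
    total = math.comb(length, 12)
    if not 1 <= N <= total:
        raise ValidationError(f"N must be in 1..{total}, got {N}")
    out = []
    r = N - 1
    x = 1
    for k in range(12, 0, -1):
        while True:
            c = math.comb(length - x, k - 1)
            if r < c:
                out.append(x)
                x += 1
                break
            r -= c
            x += 1
    return tuple(out)


def rank_pentagon_vector(positions, length: int) -> int:
    """Inverse of :func:`unrank_pentagon_vector`."""
    positions = tuple(positions)
    r = 0
    prev = 0
    for k, p in enumerate(positions):
        for x in range(prev + 1, p):
            r += math.comb(length - x, 12 - k - 1)
        prev = p
    return r + 1


def sample_many(
    n: int, n_accepts: int, rng_seed: int, max_trials: int = 200_000_000
) -> tuple[list[SpiralCode], int]:
    """Draw ``n_accepts`` uniform isomers of ``C_n`` by acceptance-rejection.

    Returns the accepted canonical codes and the total number of trials.
    The candidate sequence length is the face count ``m = n/2 + 2``.
    """
    if not is_feasible(n):
        raise ValidationError(f"infeasible n={n}")
    m = n // 2 + 2
    codes, trials, accepted = _k._sample_kernel(
        m, n_accepts, rng_seed % (2**31 - 1), max_trials
    )
    if accepted < n_accepts:
        raise RuntimeError(
            f"max_trials={max_trials} exhausted after {accepted} acceptances"
        )
    out = [SpiralCode(n, tuple(int(x) for x in codes[i])) for i in range(accepted)]
    return out, int(trials)


def sample_rejection(n: int, rng_seed: int, max_trials: int = 200_000_000):
    """One uniform random ``C_n`` isomer plus the trial count."""
    codes, trials = sample_many(n, 1, rng_seed, max_trials)
    return windup(codes[0]), trials


def acceptance_rate(n: int, convention: str = "faces") -> float:
    """Expected acceptance rate of the rejection sampler.

    ``convention='faces'`` uses candidate sequences of length ``n/2 + 2`` (the
    face count, the package default); ``convention='vertices'`` uses length
    ``n`` sequences, the dialect under which the often-quoted ~1e-9 rate for
    n = 60 arises.
    """
    length = n // 2 + 2 if convention == "faces" else n
    return isomer_count(n) / math.comb(length, 12)
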