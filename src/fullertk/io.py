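"""Readers and writers for the formats the toolkit speaks.

* *planar code*: the compact binary stream used by the cubic-planar-graph
  generation ecosystem (``>>planar_code<<`` header, per graph a vertex count
  followed by each vertex's clockwise neighbour list, 1-based,
  zero-terminated);
* *spiral files*: one isomer per line, ``n: p1 p2 ... p12`` with 1-based
  pentagon positions;
* *rotation files*: a human-readable rotation system, one vertex per line
  ``id: n1 n2 n3 ...`` in counterclockwise order;
* :func:`fixtures`: a validated set of named reference graphs used across
  the experiments.
"""

from __future__ import annotations

import io as _io
from functools import lru_cache

from .embedding import PlanarEmbedding, ValidationError
from .families import chamfer, construction2, construction3, goldberg, nanotube_5_0
from .fullerene import DualTriangulation, dualize
from .spiral import SpiralCode, enumerate_codes, windup_dual

__all__ = [
    "read_planar_code",
    "write_planar_code",
    "read_spiral_file",
    "write_spiral_file",
    "read_rotation_file",
    "write_rotation_file",
    "fixtures",
]

_HEADER = b">>planar_code<<"


def write_planar_code(graphs, stream=None) -> bytes:
    """Encode embeddings as a planar_code byte stream (<= 255 vertices)."""
    buf = stream or _io.BytesIO()
    buf.write(_HEADER)
    for emb in graphs:
        n = emb.num_vertices
        if n > 255:
            raise ValidationError("planar code writer supports up to 255 vertices")
        buf.write(bytes([n]))
        for nbrs in emb.rotation:
            # stored clockwise, 1-based
            buf.write(bytes(v + 1 for v in reversed(nbrs)))
            buf.write(b"\x00")
    return buf.getvalue() if stream is None else b""


def read_planar_code(data) -> list[PlanarEmbedding]:
    """Decode a planar_code byte stream into validated embeddings."""
    if hasattr(data, "read"):
        data = data.read()
    if not data:
        return []
    if not data.startswith(_HEADER):
        raise ValidationError("missing >>planar_code<< header at byte 0")
    pos = len(_HEADER)
    out = []
    while pos < len(data):
        n = data[pos]
        pos += 1
        if n == 0:
            raise ValidationError(f"zero vertex count at byte {pos - 1}")
        rotation = []
        for v in range(n):
            nbrs = []
            while True:
                if pos >= len(data):
                    raise ValidationError(
                        f"truncated neighbour list of vertex {v} at byte {pos}"
                    )
                b = data[pos]
                pos += 1
                if b == 0:
                    break
                nbrs.append(b - 1)
            rotation.append(tuple(reversed(nbrs)))  # stored clockwise
        out.append(PlanarEmbedding.from_rotation(rotation))
    return out


def write_spiral_file(codes, path=None) -> str:
    lines = [
        f"{c.n}: " + " ".join(str(p) for p in c.pentagon_positions)
        for c in codes
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_spiral_file(source) -> list[SpiralCode]:
    """Parse ``n: p1 ... p12`` lines (whitespace tolerant, # comments)."""
    if hasattr(source, "read"):
        text = source.read()
    elif "\n" in str(source) or ":" in str(source):
        text = str(source)
    else:
        with open(source) as fh:
            text = fh.read()
    out = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            head, tail = line.split(":", 1)
            n = int(head)
            positions = tuple(int(x) for x in tail.split())
        except ValueError as exc:
            raise ValidationError(f"line {ln}: cannot parse {line!r}") from exc
        if len(positions) != 12:
            raise ValidationError(
                f"line {ln}: expected 12 pentagon positions, got {len(positions)}"
            )
        if list(positions) != sorted(positions):
            raise ValidationError(f"line {ln}: positions must be increasing")
        out.append(SpiralCode(n, positions))
    return out


def write_rotation_file(emb: PlanarEmbedding, path=None) -> str:
    """Serialize a rotation system, one ``id: neighbours...`` line per vertex.

    Vertex ids are 0-based; neighbour order is counterclockwise.
    """
    lines = ["# rotation system, 0-based ids, counterclockwise neighbour order"]
    lines += [
        f"{v}: " + " ".join(str(w) for w in nbrs)
        for v, nbrs in enumerate(emb.rotation)
    ]
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_rotation_file(source) -> PlanarEmbedding:
    if hasattr(source, "read"):
        text = source.read()
    elif "\n" in str(source) or ":" in str(source):
        text = str(source)
    else:
        with open(source) as fh:
            text = fh.read()
    rows = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            head, tail = line.split(":", 1)
            v = int(head)
            rows[v] = tuple(int(x) for x in tail.split())
        except ValueError as exc:
            raise ValidationError(f"line {ln}: cannot parse {line!r}") from exc
    if sorted(rows) != list(range(len(rows))):
        raise ValidationError("vertex ids must be contiguous from 0")
    return PlanarEmbedding.from_rotation([rows[v] for v in range(len(rows))])


@lru_cache(maxsize=1)
def fixtures() -> dict[str, DualTriangulation]:
    """Named, validated reference duals used throughout the experiments."""
    out = {
        "C20": windup_dual(enumerate_codes(20)[0]),
        "C24": windup_dual(enumerate_codes(24)[0]),
        "C36_1": dualize(construction3(36)),
        "C56_622": windup_dual(enumerate_codes(56)[621]),
        "construction2_t2": construction2(2),
        "nanotube50_60": dualize(nanotube_5_0(60)),
        "goldberg_1_1": dualize(goldberg(1, 1)),
        "goldberg_2_0": dualize(goldberg(2, 0)),
        "chamfer_C24": chamfer(windup_dual(enumerate_codes(24)[0])),
    }
    for t in out.values():
        t.validate()
    return out
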