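"""Construction of the supramolecular Fuchsine sheet graph F[m,n].

A single Fuchsine unit is modelled as a 40-vertex, 42-edge graph whose
edge partition is {(3,3): 24, (1,3): 18}: a 22-cycle with two chords (so
four cycle vertices get degree 3 from a chord) and one pendant vertex on
each of the remaining 18 cycle vertices.  Degree-based indices depend only
on this partition, not on the atom-level drawing, so any unit realising it
yields the same sheet indices (a property the test-suite checks for an
alternative chord placement).

The m x n sheet is assembled on a grid of unit copies: the E pendant
("port") of unit (i, j) is fused with the W port of unit (i+1, j) along a
row, and the S port of (i, j) with the N port of (i, j+1) across rows.
Fusion identifies the two pendant vertices into one degree-2 connector
vertex, so every junction removes one vertex and no edges:

    |V(F[m,n])| = 40*m*n - (2*m*n - m - n) = 38*m*n + m + n
    |E(F[m,n])| = 42*m*n

and each junction converts two (1,3) edges into two (2,3) edges, giving the
sheet partition

    (3,3): 24mn,   (1,3): 14mn + 2(m+n),   (2,3): 4mn - 2m - 2n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import networkx as nx

from .graph_core import EdgePartition, edge_partition, validate

PORT_NAMES = ("W", "E", "N", "S")

#: edge partition every valid unit template must realise
UNIT_PARTITION = {(3, 3): 24, (1, 3): 18}
UNIT_VERTICES = 40
UNIT_EDGES = 42

CANONICAL_CHORDS = ((0, 11), (5, 16))
_PORT_LOCALS = {"W": "p2", "E": "p13", "N": "p8", "S": "p19"}
_RING = 22


class TemplateError(ValueError):
    """Raised for malformed or invariant-violating unit templates."""


@dataclass(frozen=True)
class UnitTemplate:
    """A Fuchsine unit graph plus its four designated attachment pendants."""

    graph: nx.Graph
    ports: Mapping[str, Hashable]

    def violations(self) -> list[str]:
        g = self.graph
        out = validate(g)
        if g.number_of_nodes() != UNIT_VERTICES:
            out.append(f"unit has {g.number_of_nodes()} vertices, expected {UNIT_VERTICES}")
        if g.number_of_edges() != UNIT_EDGES:
            out.append(f"unit has {g.number_of_edges()} edges, expected {UNIT_EDGES}")
        part = edge_partition(g)
        if part != UNIT_PARTITION:
            out.append(f"unit edge partition {part.counts} != {UNIT_PARTITION}")
        if sorted(self.ports) != sorted(PORT_NAMES):
            out.append(f"ports must be exactly {PORT_NAMES}, got {tuple(self.ports)}")
        else:
            seen = set()
            for name in PORT_NAMES:
                v = self.ports[name]
                if v in seen:
                    out.append(f"port {name} reuses vertex {v!r}")
                seen.add(v)
                if v not in g:
                    out.append(f"port {name} vertex {v!r} not in graph")
                elif g.degree(v) != 1:
                    out.append(f"port {name} vertex {v!r} has degree {g.degree(v)}, not pendant")
                elif g.degree(next(iter(g[v]))) != 3:
                    out.append(f"port {name} neighbour does not have degree 3")
        return out

    def require_valid(self) -> "UnitTemplate":
        probs = self.violations()
        if probs:
            raise TemplateError("; ".join(probs))
        return self


def canonical_unit(
    chords: tuple[tuple[int, int], ...] = CANONICAL_CHORDS,
) -> UnitTemplate:
    """The canonical 40-vertex unit: a 22-cycle ``c0..c21``, two chords, and
    one pendant ``p<i>`` on every cycle vertex without a chord.

    ``chords`` may be overridden (e.g. ``((0, 11), (3, 14))``) to obtain an
    alternative unit with the identical edge partition; endpoints must be
    four distinct cycle positions avoiding the port positions 2, 8, 13, 19.
    """
    ends = [v for ch in chords for v in ch]
    if len(chords) != 2 or len(set(ends)) != 4:
        raise TemplateError(f"need two chords with four distinct endpoints, got {chords}")
    if any(not 0 <= v < _RING for v in ends):
        raise TemplateError(f"chord endpoints must lie on the 22-cycle, got {chords}")
    port_positions = {2, 8, 13, 19}
    if port_positions & set(ends):
        raise TemplateError(f"chords {chords} collide with port pendants at {sorted(port_positions)}")
    for u, v in chords:
        if abs(u - v) in (1, _RING - 1):
            raise TemplateError(f"chord {(u, v)} duplicates a cycle edge")

    g = nx.Graph()
    for i in range(_RING):
        g.add_edge(f"c{i}", f"c{(i + 1) % _RING}")
    for u, v in chords:
        g.add_edge(f"c{u}", f"c{v}")
    for i in range(_RING):
        if i not in set(ends):
            g.add_edge(f"c{i}", f"p{i}")
    ports = dict(_PORT_LOCALS)
    return UnitTemplate(graph=g, ports=ports).require_valid()


@dataclass(frozen=True)
class SheetSpec:
    """Dimensions and unit template of a sheet: m columns by n rows of units."""

    m: int
    n: int
    template: UnitTemplate = field(default_factory=canonical_unit)

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError(f"sheet dimensions require m, n >= 1, got m={self.m}, n={self.n}")


def fuse_pendants(
    g: nx.Graph,
    u: Hashable,
    v: Hashable,
    new_label: Hashable | None = None,
) -> nx.Graph:
    """Identify two pendant vertices into a single degree-2 connector.

    Returns a new graph in which ``u`` and ``v`` are replaced by one vertex
    adjacent to both of their former neighbours; the vertex count drops by
    one and the edge count is unchanged.
    """
    if u == v:
        raise ValueError("cannot fuse a pendant with itself")
    for x in (u, v):
        if x not in g:
            raise ValueError(f"vertex {x!r} not in graph")
        if g.degree(x) != 1:
            raise ValueError(f"vertex {x!r} has degree {g.degree(x)}, not a pendant")
    nu, nv = next(iter(g[u])), next(iter(g[v]))
    if nu == nv:
        raise ValueError(f"pendants {u!r} and {v!r} hang off the same vertex {nu!r}")
    out = g.copy()
    _fuse_inplace(out, u, v, new_label)
    return out


def _fuse_inplace(g: nx.Graph, u: Hashable, v: Hashable, new_label: Hashable | None = None) -> None:
    nu, nv = next(iter(g[u])), next(iter(g[v]))
    w = new_label if new_label is not None else f"{u}+{v}"
    g.remove_nodes_from([u, v])
    g.add_edge(w, nu)
    g.add_edge(w, nv)


def _unit_copy_label(i: int, j: int, local: Hashable) -> str:
    return f"{i}.{j}:{local}"


def build_sheet(
    m: int | SheetSpec,
    n: int | None = None,
    template: UnitTemplate | None = None,
) -> nx.Graph:
    """Assemble F[m,n] from an m x n grid of unit copies by pendant fusion.

    Accepts either ``build_sheet(spec)`` or ``build_sheet(m, n[, template])``.
    Vertex labels encode (column, row, local-name) provenance as
    ``"i.j:local"``; fused connector vertices carry both parents' labels.
    Construction is deterministic: identical labels across runs.
    """
    if isinstance(m, SheetSpec):
        spec = m
    else:
        if n is None:
            raise TypeError("build_sheet needs n when m is an integer")
        spec = SheetSpec(m, n, template if template is not None else canonical_unit())
    spec.template.require_valid()
    mm, nn, tmpl = spec.m, spec.n, spec.template

    g = nx.Graph()
    for j in range(1, nn + 1):
        for i in range(1, mm + 1):
            for u, v in tmpl.graph.edges:
                g.add_edge(_unit_copy_label(i, j, u), _unit_copy_label(i, j, v))

    def port(i: int, j: int, name: str) -> str:
        return _unit_copy_label(i, j, tmpl.ports[name])

    # E-W fusion within each row, then S-N fusion between consecutive rows.
    # Ports are pendants by the template invariant, so fuse in place.
    for j in range(1, nn + 1):
        for i in range(1, mm):
            _fuse_inplace(g, port(i, j, "E"), port(i + 1, j, "W"))
    for j in range(1, nn):
        for i in range(1, mm + 1):
            _fuse_inplace(g, port(i, j, "S"), port(i, j + 1, "N"))
    return g


def sheet_partition(m: int, n: int) -> EdgePartition:
    """The closed-form edge partition of F[m,n] (no graph is built)."""
    if m < 1 or n < 1:
        raise ValueError(f"require m, n >= 1, got m={m}, n={n}")
    return EdgePartition(
        {
            (3, 3): 24 * m * n,
            (1, 3): 14 * m * n + 2 * (m + n),
            (2, 3): n * (2 * m - 2) + 2 * m * (n - 1),
        }
    )


# ---------------------------------------------------------------------------
# Template file IO
# ---------------------------------------------------------------------------
#
# Format: plain text, one record per line.
#   # comment
#   edge <u> <v>
#   port W|E|N|S <v>
# Vertex names are arbitrary whitespace-free tokens.


def write_template(t: UnitTemplate, path: str | Path) -> None:
    lines = ["# Fuchsine unit template"]
    lines += [f"edge {u} {v}" for u, v in sorted((sorted(map(str, e)) for e in t.graph.edges))]
    lines += [f"port {name} {t.ports[name]}" for name in PORT_NAMES]
    Path(path).write_text("\n".join(lines) + "\n")


def read_template(path: str | Path) -> UnitTemplate:
    path = Path(path)
    g = nx.Graph()
    ports: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "edge":
            if len(parts) != 3:
                raise TemplateError(f"{path}:{lineno}: expected 'edge u v', got {raw!r}")
            u, v = parts[1], parts[2]
            if u == v:
                raise TemplateError(f"{path}:{lineno}: self-loop edge {u!r}")
            if g.has_edge(u, v):
                raise TemplateError(f"{path}:{lineno}: duplicate edge {u!r} {v!r}")
            g.add_edge(u, v)
        elif parts[0] == "port":
            if len(parts) != 3 or parts[1] not in PORT_NAMES:
                raise TemplateError(
                    f"{path}:{lineno}: expected 'port W|E|N|S v', got {raw!r}"
                )
            if parts[1] in ports:
                raise TemplateError(f"{path}:{lineno}: duplicate port {parts[1]}")
            ports[parts[1]] = parts[2]
        else:
            raise TemplateError(f"{path}:{lineno}: unknown record {parts[0]!r}")
    t = UnitTemplate(graph=g, ports=ports)
    probs = t.violations()
    if probs:
        raise TemplateError(f"{path}: " + "; ".join(probs))
    return t
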