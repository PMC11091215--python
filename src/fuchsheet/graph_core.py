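"""Core graph plumbing: degrees, edge partitions, validation, and IO.

Molecular graphs are plain :class:`networkx.Graph` objects (simple,
undirected, unweighted).  The central device is the *edge partition*: the
tally of edges by the canonical pair of endpoint degrees.  It is a
sufficient statistic for every degree-based topological index, so most of
the package only ever looks at graphs through :func:`edge_partition`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterator, Mapping

import networkx as nx

DegreePair = tuple[int, int]


def canonical_pair(d_u: int, d_v: int) -> DegreePair:
    """Order an endpoint-degree pair as (lo, hi)."""
    return (d_u, d_v) if d_u <= d_v else (d_v, d_u)


def degree_map(g: nx.Graph) -> dict[Hashable, int]:
    """Vertex -> degree.  Empty graph yields an empty map."""
    return dict(g.degree())


@dataclass(frozen=True)
class EdgePartition:
    """Multiset of canonical endpoint-degree pairs of a graph's edges.

    ``counts`` maps (lo, hi) with lo <= hi to a positive tally; pairs with
    zero count are not stored, and equality ignores explicit zero entries so
    that ``{(3,3): 24, (1,3): 18}`` equals ``{(3,3): 24, (1,3): 18, (2,3): 0}``.
    """

    counts: Mapping[DegreePair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[DegreePair, int] = {}
        for pair, cnt in self.counts.items():
            if cnt < 0:
                raise ValueError(f"negative count for {pair}")
            lo, hi = pair
            if lo > hi:
                raise ValueError(f"non-canonical pair {pair}")
            if cnt:
                cleaned[pair] = int(cnt)
        object.__setattr__(self, "counts", dict(sorted(cleaned.items())))

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "EdgePartition":
        deg = g.degree
        tally: Counter[DegreePair] = Counter(
            canonical_pair(deg(u), deg(v)) for u, v in g.edges
        )
        return cls(tally)

    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, pair: DegreePair) -> int:
        return self.counts.get(canonical_pair(*pair), 0)

    def items(self) -> Iterator[tuple[DegreePair, int]]:
        return iter(self.counts.items())

    def __eq__(self, other: object) -> bool:
        if isinstance(other, EdgePartition):
            return self.counts == other.counts
        if isinstance(other, Mapping):
            theirs = {
                canonical_pair(*p): c for p, c in other.items() if c
            }
            return self.counts == theirs
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self.counts.items()))

    def __repr__(self) -> str:
        return f"EdgePartition({self.counts!r})"


def edge_partition(g: nx.Graph) -> EdgePartition:
    """Tally every edge by the canonical degree pair of its endpoints."""
    return EdgePartition.from_graph(g)


def validate(g: nx.Graph) -> list[str]:
    """Check that ``g`` is a simple connected undirected graph.

    Returns a list of human-readable violations; an empty list means valid.
    Violations are data, not exceptions -- callers decide how strict to be.
    """
    problems: list[str] = []
    if g.is_directed():
        problems.append("graph is directed; expected undirected")
    if g.is_multigraph():
        problems.append("graph is a multigraph; expected simple")
    for v in nx.nodes_with_selfloops(g):
        problems.append(f"self-loop at vertex {v!r}")
    if g.number_of_nodes() > 0 and not g.is_directed() and not g.is_multigraph():
        if not nx.is_connected(g):
            comps = list(nx.connected_components(g))
            smallest = min(comps, key=len)
            problems.append(
                f"graph is disconnected ({len(comps)} components; "
                f"e.g. component containing {sorted(map(str, smallest))[0]!r})"
            )
    return problems


# ---------------------------------------------------------------------------
# IO: deterministic edge-list and GraphML writers
# ---------------------------------------------------------------------------


def _sorted_edges(g: nx.Graph) -> list[tuple[str, str]]:
    pairs = []
    for u, v in g.edges:
        su, sv = str(u), str(v)
        pairs.append((su, sv) if su <= sv else (sv, su))
    return sorted(pairs)


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    """Tab-separated ``u<TAB>v`` lines under a ``# vertices= edges=`` header.

    Vertex labels are stringified; output order is sorted, hence identical
    across runs for identically-labelled graphs.
    """
    lines = [f"# vertices={g.number_of_nodes()} edges={g.number_of_edges()}"]
    lines += [f"{u}\t{v}" for u, v in _sorted_edges(g)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    """Inverse of :func:`write_edgelist`; validates the header counts."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# vertices="):
        raise ValueError(f"{path}: missing '# vertices=<N> edges=<M>' header")
    head = lines[0].lstrip("# ").split()
    try:
        n_decl = int(head[0].split("=")[1])
        m_decl = int(head[1].split("=")[1])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed header {lines[0]!r}") from exc
    g = nx.Graph()
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'u<TAB>v', got {line!r}")
        g.add_edge(parts[0], parts[1])
    if g.number_of_nodes() != n_decl:
        raise ValueError(
            f"{path}: header declares {n_decl} vertices, found {g.number_of_nodes()}"
        )
    if g.number_of_edges() != m_decl:
        raise ValueError(
            f"{path}: header declares {m_decl} edges, found {g.number_of_edges()}"
        )
    return g


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export with stringified vertex labels."""
    relabelled = nx.relabel_nodes(g, {v: str(v) for v in g.nodes}, copy=True)
    nx.write_graphml(relabelled, str(path))
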