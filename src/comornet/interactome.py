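"""Protein-protein interaction network assembly and queries.

The interactome is a union of edge lists drawn from heterogeneous sources
(pathway databases, physical-interaction screens, regulatory networks), so
edges may be directed or undirected and may carry an activation/inhibition
sign or leave it unknown. Undirected edges are stored canonically with
sorted endpoints; duplicates across sources are merged with provenance
union. Path enumeration respects direction on directed edges and traverses
undirected edges both ways.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from comornet.characterization import normalize_symbol

SIGN_UNKNOWN = 0

__all__ = [
    "Edge",
    "Interactome",
    "InteractomeError",
    "assemble_interactome",
    "write_edge_dump",
    "enumerate_paths",
    "randomize_degree_preserving",
]


class InteractomeError(ValueError):
    """Raised on malformed edge input or impossible network operations."""


@dataclass(frozen=True)
class Edge:
    """One interaction. ``sign`` is +1 (activating), -1 (inhibiting) or 0 (unknown)."""

    source: str
    target: str
    directed: bool = False
    sign: int = SIGN_UNKNOWN
    sources: frozenset[str] = frozenset()

    def key(self) -> tuple[str, str, bool]:
        if self.directed:
            return (self.source, self.target, True)
        a, b = sorted((self.source, self.target))
        return (a, b, False)


class Interactome:
    """Deduplicated protein graph with optional per-edge sign/direction."""

    def __init__(self, edges: Iterable[Edge] = (), nodes: Iterable[str] = ()):
        self._edges: dict[tuple[str, str, bool], Edge] = {}
        self._adj: dict[str, set[str]] = {}
        for node in nodes:
            self._adj.setdefault(node, set())
        for edge in edges:
            self.add_edge(edge)

    # -- construction -------------------------------------------------------

    def add_edge(self, edge: Edge) -> None:
        key = edge.key()
        if not edge.directed and edge.key() != (edge.source, edge.target, False):
            edge = replace(edge, source=key[0], target=key[1])
        if key in self._edges:
            old = self._edges[key]
            sign = old.sign if old.sign != SIGN_UNKNOWN else edge.sign
            self._edges[key] = replace(old, sign=sign, sources=old.sources | edge.sources)
        else:
            self._edges[key] = edge
        self._adj.setdefault(edge.source, set()).add(edge.target)
        self._adj.setdefault(edge.target, set()).add(edge.source)
        self.__dict__.pop("_diameter_cache", None)

    # -- basic queries -------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._adj)

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(self._edges[k] for k in sorted(self._edges))

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def neighbors(self, gene: str) -> set[str]:
        """Adjacent nodes ignoring edge direction; unknown gene -> empty set."""
        return set(self._adj.get(gene, ())) - {gene}

    def degree(self, gene: str) -> int:
        return len(self.neighbors(gene))

    def edge_between(self, a: str, b: str) -> Edge | None:
        """The edge usable to step from ``a`` to ``b`` (direction respected)."""
        directed = self._edges.get((a, b, True))
        if directed is not None:
            return directed
        lo, hi = sorted((a, b))
        return self._edges.get((lo, hi, False))

    def successors(self, gene: str) -> set[str]:
        """Nodes reachable from ``gene`` in one step, respecting direction."""
        return {n for n in self._adj.get(gene, ()) if self.edge_between(gene, n) is not None} - {gene}

    # -- networkx views ------------------------------------------------------

    def to_undirected_nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self._adj))
        for edge in self._edges.values():
            g.add_edge(edge.source, edge.target)
        return g

    def to_traversal_nx(self) -> nx.DiGraph:
        """Directed view where each undirected edge appears as both arcs."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self._adj))
        for edge in self._edges.values():
            g.add_edge(edge.source, edge.target)
            if not edge.directed:
                g.add_edge(edge.target, edge.source)
        return g

    def diameter(self) -> int:
        """Diameter of the largest connected component (direction ignored); cached."""
        cached = self.__dict__.get("_diameter_cache")
        if cached is None:
            g = self.to_undirected_nx()
            if g.number_of_nodes() == 0:
                cached = 0
            else:
                comp = max(nx.connected_components(g), key=len)
                cached = nx.diameter(g.subgraph(comp)) if len(comp) > 1 else 0
            self.__dict__["_diameter_cache"] = cached
        return cached


def _parse_edge_row(fields: Sequence[str], provenance: str) -> Edge:
    if len(fields) == 2:
        a, b = fields
        relation = None
    elif len(fields) == 3:
        a, relation, b = fields
    else:
        raise InteractomeError(f"malformed row {fields!r}: expected 2 or 3 columns")
    src, _ = normalize_symbol(a)
    dst, _ = normalize_symbol(b)
    directed = False
    sign = SIGN_UNKNOWN
    if relation:
        rel = relation.strip().lower()
        if rel in {"activates", "activation", "->", "stimulates"}:
            directed, sign = True, 1
        elif rel in {"inhibits", "inhibition", "-|", "represses"}:
            directed, sign = True, -1
        elif rel in {"regulates", "directed"}:
            directed = True
    return Edge(source=src, target=dst, directed=directed, sign=sign, sources=frozenset({provenance}))


def assemble_interactome(edge_tables: Mapping[str, str | Path] | Sequence[tuple[str, str | Path]]) -> Interactome:
    """Union edge-list files into one deduplicated interactome.

    ``edge_tables`` maps a provenance tag to a SIF ("A rel B") or 2/3-column
    TSV file. Duplicate edges are merged with provenance union; symbols are
    case-normalized.
    """
    items = edge_tables.items() if isinstance(edge_tables, Mapping) else edge_tables
    net = Interactome()
    for tag, path in items:
        text = Path(path).read_text(encoding="utf-8")
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                net.add_edge(_parse_edge_row(fields, tag))
            except InteractomeError as exc:
                raise InteractomeError(f"{path}:{lineno}: {exc}") from exc
    if net.n_edges == 0:
        raise InteractomeError("no edges parsed from any input table")
    return net


def write_edge_dump(net: Interactome, path: str | Path) -> None:
    """Write a TSV edge dump (source, target, directed, sign, provenance)."""
    lines = ["source\ttarget\tdirected\tsign\tprovenance"]
    for edge in net.edges:
        prov = ",".join(sorted(edge.sources))
        lines.append(f"{edge.source}\t{edge.target}\t{int(edge.directed)}\t{edge.sign}\t{prov}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_edge_dump(path: str | Path) -> Interactome:
    """Read back a dump written by :func:`write_edge_dump`."""
    net = Interactome()
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        src, dst, directed, sign, prov = line.split("\t")
        tags = frozenset(t for t in prov.split(",") if t)
        net.add_edge(Edge(src, dst, directed=bool(int(directed)), sign=int(sign), sources=tags))
    if net.n_edges == 0:
        raise InteractomeError(f"{path}: empty edge dump")
    return net


def enumerate_paths(
    net: Interactome,
    sources: Iterable[str],
    sinks: Iterable[str],
    max_edges: int = 3,
    exact: bool = False,
) -> list[list[str]]:
    """All simple paths from any source to any sink with at most ``max_edges``
    edges (exactly ``max_edges`` if ``exact``), in lexicographic order.

    Direction is respected on directed edges; undirected edges may be
    traversed both ways. Sources that are themselves sinks do not produce a
    zero-length path.
    """
    if max_edges < 1:
        raise InteractomeError("max_edges must be >= 1")
    src_set = sorted(set(sources) & net.nodes)
    sink_set = set(sinks) & net.nodes
    if not src_set or not sink_set:
        return []

    paths: list[list[str]] = []

    def dfs(path: list[str], visited: set[str]) -> None:
        node = path[-1]
        n_edges = len(path) - 1
        if node in sink_set and n_edges >= 1 and (not exact or n_edges == max_edges):
            paths.append(list(path))
        if n_edges == max_edges:
            return
        for nxt in sorted(net.successors(node)):
            if nxt in visited:
                continue
            path.append(nxt)
            visited.add(nxt)
            dfs(path, visited)
            visited.remove(nxt)
            path.pop()

    for s in src_set:
        dfs([s], {s})
    return sorted(paths)


def randomize_degree_preserving(net: Interactome, n_swaps: int, seed: int) -> Interactome:
    """Degree-preserving edge rewiring (double-edge swaps) as a null model.

    Direction, sign and provenance are dropped: the null network is an
    unsigned undirected graph with the same degree sequence. ``n_swaps = 0``
    returns the same edge set.
    """
    if n_swaps < 0:
        raise InteractomeError("n_swaps must be >= 0")
    g = net.to_undirected_nx()
    if n_swaps > 0:
        if g.number_of_edges() < 2:
            raise InteractomeError("graph too small to swap (< 2 independent edges)")
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=max(100, 50 * n_swaps), seed=seed)
    return Interactome(
        edges=(Edge(a, b) for a, b in g.edges()),
        nodes=g.nodes(),
    )
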