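"""Graph data model, validation, and readers/writers for anatomical networks.

Networks are undirected, unweighted simple graphs whose nodes are string
labels (bone names are the interface — no integer re-indexing is exposed).
Each node may carry a laterality flag: ``L`` (left), ``R`` (right) or ``U``
(unpaired/midline, the default).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "AnatomicalNetwork",
    "ValidationReport",
    "DegreeSplit",
    "read_network",
    "write_network",
    "validate_network",
    "degree_split",
]

_LATERALITY = frozenset({"L", "R", "U"})


def _canon_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class AnatomicalNetwork:
    """An undirected, unweighted simple graph with optional node laterality.

    Parameters
    ----------
    nodes:
        Unique, non-empty string labels.
    edges:
        Unordered label pairs; stored canonically sorted within each pair.
    laterality:
        Optional map ``node -> {"L", "R", "U"}``; missing nodes default to
        ``"U"``.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    laterality: Mapping[str, str] = field(default_factory=dict)

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
        laterality: Mapping[str, str] | None = None,
    ) -> None:
        node_tuple = tuple(nodes)
        seen = set()
        for n in node_tuple:
            if not isinstance(n, str) or not n:
                raise ValueError(f"node labels must be non-empty strings, got {n!r}")
            if n in seen:
                raise ValueError(f"duplicate node label: {n!r}")
            seen.add(n)
        if not node_tuple:
            raise ValueError("a network needs at least one node")
        canon = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r} is not allowed")
            if a not in seen or b not in seen:
                raise ValueError(f"edge ({a!r}, {b!r}) references an undeclared node")
            canon.add(_canon_edge(a, b))
        side = {}
        for n, s in (laterality or {}).items():
            if n not in seen:
                raise ValueError(f"laterality given for unknown node {n!r}")
            if s not in _LATERALITY:
                raise ValueError(f"laterality must be L/R/U, got {s!r} for {n!r}")
            side[n] = s
        object.__setattr__(self, "nodes", node_tuple)
        object.__setattr__(self, "edges", frozenset(canon))
        object.__setattr__(self, "laterality", dict(side))

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def side(self, node: str) -> str:
        return self.laterality.get(node, "U")

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    def neighbors(self, node: str) -> set[str]:
        if node not in set(self.nodes):
            raise KeyError(node)
        out = set()
        for a, b in self.edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def has_edge(self, a: str, b: str) -> bool:
        return _canon_edge(a, b) in self.edges

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    # -- conversions ---------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, side=self.side(n))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "AnatomicalNetwork":
        side = {
            str(n): d["side"]
            for n, d in g.nodes(data=True)
            if d.get("side") in _LATERALITY
        }
        return cls(
            nodes=[str(n) for n in g.nodes()],
            edges=[(str(a), str(b)) for a, b in g.edges()],
            laterality=side,
        )


@dataclass(frozen=True)
class ValidationReport:
    is_simple: bool
    is_connected: bool
    n_nodes: int
    n_edges: int
    components: tuple[frozenset[str], ...]
    warnings: tuple[str, ...]


@dataclass(frozen=True)
class DegreeSplit:
    """Per-node split of its links into those toward a reference node set
    (``in_links``) and those toward its complement (``out_links``)."""

    node: str
    in_links: int
    out_links: int

    @property
    def difference(self) -> int:
        return self.in_links - self.out_links


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_network(path: str | Path, format: str = "graphml") -> AnatomicalNetwork:
    """Read a network from ``graphml`` or ``edgelist-csv``.

    Edge direction in the source is ignored; duplicate (anti-)parallel edges
    are collapsed with a warning; self-loops are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        raw_edges = [(str(a), str(b)) for a, b in g.edges()]
        nodes = [str(n) for n in g.nodes()]
        side = {
            str(n): d["side"]
            for n, d in g.nodes(data=True)
            if d.get("side") in _LATERALITY
        }
    elif format == "edgelist-csv":
        raw_edges = []
        with path.open(newline="", encoding="utf-8") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) < 2:
                    raise ValueError(f"{path}:{i + 1}: expected two columns, got {row!r}")
                a, b = row[0].strip(), row[1].strip()
                if i == 0 and a.lower() == "source" and b.lower() == "target":
                    continue  # tolerated spreadsheet-style header
                raw_edges.append((a, b))
        nodes = []
        seen: set[str] = set()
        for a, b in raw_edges:
            for n in (a, b):
                if n not in seen:
                    seen.add(n)
                    nodes.append(n)
        side = {}
    else:
        raise ValueError(f"unknown format {format!r}; use 'graphml' or 'edgelist-csv'")

    for a, b in raw_edges:
        if a == b:
            raise ValueError(f"self-loop on node {a!r} in {path}")
    canon = [_canon_edge(a, b) for a, b in raw_edges]
    if len(set(canon)) < len(canon):
        warnings.warn(
            f"{path}: duplicate edges collapsed "
            f"({len(canon) - len(set(canon))} removed)",
            stacklevel=2,
        )
    return AnatomicalNetwork(nodes=nodes, edges=canon, laterality=side)


def write_network(net: AnatomicalNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write a network as GraphML (with the ``side`` node attribute) or as a
    headerless two-column CSV edge list (laterality is not representable)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "edgelist-csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            for a, b in sorted(net.edges):
                w.writerow([a, b])
    else:
        raise ValueError(f"unknown format {format!r}; use 'graphml' or 'edgelist-csv'")


# ---------------------------------------------------------------------------
# Validation and degree accounting
# ---------------------------------------------------------------------------

def validate_network(net: AnatomicalNetwork) -> ValidationReport:
    """Report connectivity and simple-graph status without mutating input."""
    g = net.to_networkx()
    comps = tuple(frozenset(c) for c in nx.connected_components(g))
    is_connected = len(comps) == 1
    warns = []
    if not is_connected:
        warns.append(
            f"network is disconnected ({len(comps)} components); "
            "it will be analyzed as given"
        )
    isolated = [n for n in net.nodes if net.degree(n) == 0]
    if isolated:
        warns.append(f"isolated nodes: {', '.join(sorted(isolated))}")
    return ValidationReport(
        is_simple=True,  # enforced by construction
        is_connected=is_connected,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        components=comps,
        warnings=tuple(warns),
    )


def degree_split(net: AnatomicalNetwork, members: Iterable[str]) -> list[DegreeSplit]:
    """Split every network node's links into links toward ``members`` versus
    links toward the complement.

    All network nodes are reported, members and non-members alike; for a
    member, links to other members count as ``in_links``.
    """
    mset = set(members)
    unknown = mset - set(net.nodes)
    if unknown:
        raise ValueError(f"unknown member labels: {sorted(unknown)}")
    adj = net.adjacency()
    out = []
    for n in net.nodes:
        in_links = len(adj[n] & mset)
        out.append(DegreeSplit(node=n, in_links=in_links, out_links=len(adj[n]) - in_links))
    return out
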