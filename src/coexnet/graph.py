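"""Undirected weighted graphs and hop-count path statistics.

The :class:`Network` here is deliberately small: nodes are string ids
carrying a ``node_class`` ("trait" or "transcript"), edges carry the
correlation coefficient that created them, and all traversals iterate
neighbours in sorted order so every downstream report is deterministic.

Distances are hop counts (unweighted breadth-first search), matching the
"degrees of separation" reading of network distance: two nodes k edges
apart have k − 1 intermediaries, i.e. k − 1 degrees of separation.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

from .errors import DomainError, UndefinedResultError, UnknownNodeError

#: Distance assigned to nodes in another component ("∞" in reports).
UNREACHABLE = math.inf

NODE_CLASSES = ("trait", "transcript")


class Network:
    """Undirected weighted graph with classed nodes.

    Invariants: no self-loops, symmetric adjacency, weights in [−1, 1].
    Isolated nodes are first-class members (a thresholded correlation
    network keeps every variable as a node even when nothing correlates
    with it).
    """

    __slots__ = ("_adj", "_class")

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, float]] = {}
        self._class: dict[str, str] = {}

    # -- construction ----------------------------------------------------
    def add_node(self, node: str, node_class: str = "transcript") -> None:
        if node_class not in NODE_CLASSES:
            raise DomainError(f"unknown node_class {node_class!r}")
        if node not in self._adj:
            self._adj[node] = {}
        self._class[node] = node_class

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise DomainError(f"self-loop on node {u!r} not allowed")
        w = float(weight)
        if not (-1.0 - 1e-12 <= w <= 1.0 + 1e-12):
            raise DomainError(f"edge weight {w} outside [-1, 1]")
        for node in (u, v):
            if node not in self._adj:
                self._adj[node] = {}
                self._class[node] = "transcript"
        self._adj[u][v] = w
        self._adj[v][u] = w

    # -- queries ---------------------------------------------------------
    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def nodes(self) -> list[str]:
        return sorted(self._adj)

    def node_class(self, node: str) -> str:
        self._require(node)
        return self._class[node]

    def neighbors(self, node: str) -> list[str]:
        self._require(node)
        return sorted(self._adj[node])

    def degree(self, node: str) -> int:
        """Number of distinct neighbours of ``node``."""
        self._require(node)
        return len(self._adj[node])

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u]

    def edge_weight(self, u: str, v: str) -> float:
        self._require(u)
        if v not in self._adj[u]:
            raise UnknownNodeError(f"no edge between {u!r} and {v!r}")
        return self._adj[u][v]

    def edges(self) -> list[tuple[str, str, float]]:
        """All edges as (u, v, weight) with u < v, sorted lexically."""
        out = [
            (u, v, w)
            for u, nbrs in self._adj.items()
            for v, w in nbrs.items()
            if u < v
        ]
        out.sort()
        return out

    def copy(self) -> "Network":
        other = Network()
        other._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        other._class = dict(self._class)
        return other

    def _require(self, node: str) -> None:
        if node not in self._adj:
            raise UnknownNodeError(f"unknown node {node!r}")


@dataclass
class LevelTable:
    """Cumulative breadth-first coverage from a seed node.

    ``rows[k-1] = (k, count of non-seed nodes within <= k steps)``; the
    table extends to the seed's eccentricity, where the cumulative count
    saturates at ``reachable_total`` (= size of the seed's component
    minus one; the seed itself is excluded by convention).
    """

    seed_id: str
    rows: list[tuple[int, int]] = field(default_factory=list)
    reachable_total: int = 0


def bfs_levels(net: Network, seed: str) -> dict[str, float]:
    """Hop-count distance from ``seed`` to every node.

    Returns a map over *all* nodes; nodes in other components map to the
    :data:`UNREACHABLE` sentinel (infinity).  The seed maps to 0.
    """
    net._require(seed)
    dist: dict[str, float] = {node: UNREACHABLE for node in net._adj}
    dist[seed] = 0
    queue: deque[str] = deque([seed])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in net.neighbors(u):
            if dist[v] == UNREACHABLE:
                dist[v] = du + 1
                queue.append(v)
    return dist


def level_table(net: Network, seed: str) -> LevelTable:
    """Table-of-neighbours-per-level: cumulative counts of nodes within k steps."""
    dist = bfs_levels(net, seed)
    finite = sorted(
        int(d) for node, d in dist.items() if node != seed and d != UNREACHABLE
    )
    table = LevelTable(seed_id=seed, reachable_total=len(finite))
    if not finite:
        return table
    ecc = finite[-1]
    cum = 0
    idx = 0
    for k in range(1, ecc + 1):
        while idx < len(finite) and finite[idx] <= k:
            cum += 1
            idx += 1
        table.rows.append((k, cum))
    return table


def connected_components(net: Network) -> list[list[str]]:
    """Partition of the node set into components.

    Each part is sorted lexically; parts are ordered by size descending,
    ties broken by smallest member, so "largest component" is part 0.
    """
    seen: set[str] = set()
    parts: list[list[str]] = []
    for start in net.nodes():
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in net.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    queue.append(v)
        comp.sort()
        parts.append(comp)
    parts.sort(key=lambda p: (-len(p), p[0]))
    return parts


def mean_shortest_path(net: Network, scope: str = "reachable_pairs") -> float:
    """Mean hop-count shortest path over node pairs.

    scope="reachable_pairs" averages over all unordered pairs that are
    mutually reachable (the convention for a graph known to be
    disconnected); scope="largest_component" restricts both endpoints to
    the largest component (identical average, smaller pair set when other
    components also contain edges).
    """
    if scope not in ("reachable_pairs", "largest_component"):
        raise DomainError(f"unknown scope {scope!r}")
    if net.n_edges == 0:
        raise UndefinedResultError("mean shortest path needs at least one edge")
    if scope == "largest_component":
        nodes = connected_components(net)[0]
        node_set = set(nodes)
    else:
        nodes = net.nodes()
        node_set = None
    total = 0.0
    count = 0
    for u in nodes:
        dist = bfs_levels(net, u)
        for v, d in dist.items():
            if v == u or d == UNREACHABLE:
                continue
            if node_set is not None and v not in node_set:
                continue
            total += d
            count += 1
    if count == 0:
        raise UndefinedResultError("no mutually reachable pair of nodes")
    # every unordered pair was visited twice
    return total / count


def degrees_of_separation(path_length: float) -> float:
    """Intermediaries on a shortest path: path length minus one.

    Direct neighbours (path length 1) are 0 degrees of separation apart.
    Accepts fractional input so a *mean* path length maps to a mean
    degrees-of-separation figure.
    """
    if path_length < 1:
        raise DomainError("path_length must be >= 1")
    return path_length - 1
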