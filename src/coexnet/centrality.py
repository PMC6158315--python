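"""The five-measure centrality panel: degree, betweenness, eigenvector,
closeness, PageRank.

All measures are computed from first principles on the unweighted
topology (edges either exist — correlation above threshold — or they do
not; the correlation magnitude is kept as edge weight for reporting but
does not enter the centrality arithmetic):

* betweenness — Brandes' dependency accumulation over BFS shortest-path
  DAGs, unnormalised, each unordered pair counted once;
* eigenvector — power iteration for the principal eigenvector of the
  adjacency matrix (run on A + I, which has the same eigenvectors but a
  positive-shifted spectrum, so iteration also converges on bipartite
  structures such as stars), scaled to max = 1;
* closeness — component-restricted closeness with (n − 1) normalisation,
  damped by the reachable fraction, so scores remain comparable on a
  disconnected graph: c(v) = |R(v)| / [(n − 1) · mean distance to R(v)];
* PageRank — random walk with uniform teleport, damping 0.85 by default,
  isolated nodes redistributing uniformly; scores sum to one.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ConfigError, ConvergenceError, UndefinedResultError
from .graph import Network

MEASURES = ("degree", "betweenness", "eigenvector", "closeness", "pagerank")


@dataclass
class CentralityReport:
    """Ranked view of one centrality measure (descending score, ties lexical)."""

    measure: str
    scores: dict[str, float]
    ranking: list[tuple[str, float]]


def degree_centrality(net: Network) -> dict[str, float]:
    return {node: float(net.degree(node)) for node in net.nodes()}


def betweenness(net: Network) -> dict[str, float]:
    """Unnormalised shortest-path betweenness (Brandes accumulation).

    For each node v: sum over unordered pairs {s, t} (s ≠ v ≠ t) of the
    fraction of s–t shortest paths passing through v.  Unreachable pairs
    contribute nothing; leaves score exactly zero.
    """
    score = {node: 0.0 for node in net.nodes()}
    for s in net.nodes():
        # single-source shortest-path counting
        stack: list[str] = []
        pred: dict[str, list[str]] = {node: [] for node in score}
        sigma = {node: 0.0 for node in score}
        dist = {node: -1 for node in score}
        sigma[s] = 1.0
        dist[s] = 0
        queue: deque[str] = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for v in net.neighbors(u):
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    pred[v].append(u)
        delta = {node: 0.0 for node in score}
        while stack:
            w = stack.pop()
            for u in pred[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                score[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {node: val / 2.0 for node, val in score.items()}


def _adjacency(net: Network):
    nodes = net.nodes()
    index = {node: i for i, node in enumerate(nodes)}
    rows, cols = [], []
    for u, v, _ in net.edges():
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(nodes), len(nodes))
    )
    return nodes, A


def eigenvector_centrality(
    net: Network, tol: float = 1e-10, max_iter: int = 10000
) -> dict[str, float]:
    """Principal adjacency eigenvector by power iteration, max scaled to 1.

    Nodes outside the component carrying the principal eigenvalue decay
    to ≈ 0.  Raises :class:`ConvergenceError` with the last residual if
    the iteration does not settle within ``max_iter`` sweeps.
    """
    if net.n_edges == 0:
        raise UndefinedResultError("eigenvector centrality needs at least one edge")
    nodes, A = _adjacency(net)
    n = len(nodes)
    x = np.full(n, 1.0 / np.sqrt(n))
    residual = np.inf
    for _ in range(max_iter):
        # shifted iteration: (A + I) x has the same fixed directions as A x
        y = A @ x + x
        y /= np.linalg.norm(y)
        residual = float(np.max(np.abs(y - x)))
        x = y
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} sweeps "
            f"(last residual {residual:.3e})"
        )
    x = np.abs(x)
    x /= x.max()
    return {node: float(val) for node, val in zip(nodes, x)}


def closeness(net: Network) -> dict[str, float]:
    """Reachable-fraction-damped closeness in [0, 1].

    c(v) = |R(v)| / [(n − 1) · d̄(v)] where R(v) is the set of nodes
    reachable from v and d̄(v) their mean hop distance.  On a connected
    graph this is classical (n − 1)-normalised closeness; isolated nodes
    score 0.
    """
    nodes = net.nodes()
    n = len(nodes)
    out: dict[str, float] = {}
    for v in nodes:
        if n == 1 or net.degree(v) == 0:
            out[v] = 0.0
            continue
        total = 0
        reached = 0
        dist = {v: 0}
        queue: deque[str] = deque([v])
        while queue:
            u = queue.popleft()
            for w in net.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    total += dist[w]
                    reached += 1
                    queue.append(w)
        out[v] = reached * reached / ((n - 1) * total) if total else 0.0
    return out


def pagerank(
    net: Network,
    damping: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> dict[str, float]:
    """PageRank on the undirected graph (each edge walked both ways).

    Fixed point of p = (1 − d)/n + d·(A D⁻¹)p with isolated (dangling)
    nodes redistributing their mass uniformly.  Scores are a probability
    distribution (sum to 1).
    """
    if not (0.0 <= damping < 1.0):
        raise ConfigError(f"damping must lie in [0, 1), got {damping}")
    nodes, A = _adjacency(net)
    n = len(nodes)
    if n == 0:
        return {}
    deg = np.asarray(A.sum(axis=1)).ravel()
    dangling = deg == 0
    inv_deg = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        walked = A @ (p * inv_deg)
        dangling_mass = p[dangling].sum()
        p_next = (1.0 - damping) / n + damping * (walked + dangling_mass / n)
        err = float(np.abs(p_next - p).sum())
        p = p_next
        if err < tol:
            break
    else:
        raise ConvergenceError(
            f"PageRank did not converge in {max_iter} sweeps (last change {err:.3e})"
        )
    p /= p.sum()
    return {node: float(val) for node, val in zip(nodes, p)}


_DISPATCH = {
    "degree": degree_centrality,
    "betweenness": betweenness,
    "eigenvector": eigenvector_centrality,
    "closeness": closeness,
    "pagerank": pagerank,
}


def centrality_report(
    net: Network,
    measures: tuple[str, ...] = MEASURES,
    top_k: int | None = 10,
    node_filter: str | None = None,
) -> dict[str, CentralityReport]:
    """One ranked table per measure.

    Scores are computed on the *full* network; ``node_filter`` (e.g.
    "transcript") only restricts the ranking afterwards, so trait nodes
    shape the scores of the genes listed around them without appearing in
    the gene table themselves.
    """
    reports: dict[str, CentralityReport] = {}
    for measure in measures:
        if measure not in _DISPATCH:
            raise ConfigError(f"unknown centrality measure {measure!r}")
        scores = _DISPATCH[measure](net)
        ranked = [
            (node, score)
            for node, score in scores.items()
            if node_filter is None or net.node_class(node) == node_filter
        ]
        ranked.sort(key=lambda t: (-t[1], t[0]))
        if top_k is not None:
            ranked = ranked[:top_k]
        reports[measure] = CentralityReport(
            measure=measure, scores=scores, ranking=ranked
        )
    return reports
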