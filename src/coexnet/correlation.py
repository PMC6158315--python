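"""Pairwise Pearson correlation, ranked correlate tables, thresholded networks.

Correlations are computed over pairwise-complete observations: for each
variable pair only the strains where *both* values are present enter the
sums.  A pair with fewer than ``min_obs`` complete observations, or with
a zero-variance side, has an *undefined* correlation — it never creates
an edge and never contributes to a node's degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AlignedDataset
from .errors import DomainError, ShapeError, UnknownNodeError
from .graph import Network

log = logging.getLogger(__name__)

#: default minimum pairwise-complete observations for a defined r
DEFAULT_MIN_OBS = 5

_VAR_EPS = 1e-14  # below this a variable counts as constant


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with per-pair observation counts.

    ``node_ids`` lists traits first, then transcripts.  ``r`` holds NaN
    where a correlation is undefined (too few complete pairs, or a
    constant variable).  ``n_obs`` holds the pairwise-complete counts.
    """

    node_ids: list[str]
    node_class: dict[str, str]
    r: np.ndarray
    n_obs: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {node: i for i, node in enumerate(self.node_ids)}

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def value(self, u: str, v: str) -> float:
        """r between two nodes (NaN if undefined)."""
        return float(self.r[self._loc(u), self._loc(v)])

    def _loc(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise UnknownNodeError(f"unknown node {node!r}") from None

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: node_a, node_b, r, n_obs for each defined pair."""
        rows = []
        n = len(self.node_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isfinite(self.r[i, j]):
                    a, b = sorted((self.node_ids[i], self.node_ids[j]))
                    rows.append((a, b, self.r[i, j], int(self.n_obs[i, j])))
        rows.sort(key=lambda t: (t[0], t[1]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "n_obs"])


@dataclass
class CorrelateTable:
    """Ranked correlates of one seed node (descending r, ties lexical)."""

    seed_id: str
    rows: list[tuple[str, float]]


def pearson_r(x, y, min_obs: int = DEFAULT_MIN_OBS) -> float:
    """Pearson's r over pairwise-complete positions; NaN when undefined.

    Undefined means fewer than ``min_obs`` complete pairs or a constant
    side.  ``min_obs`` must be at least 3 (two points always correlate
    perfectly).
    """
    if min_obs < 3:
        raise DomainError("min_obs must be >= 3")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_obs:
        return float("nan")
    xs = x[mask] - x[mask].mean()
    ys = y[mask] - y[mask].mean()
    vx = float(xs @ xs)
    vy = float(ys @ ys)
    if vx <= _VAR_EPS * n or vy <= _VAR_EPS * n:
        return float("nan")
    return float(np.clip((xs @ ys) / np.sqrt(vx * vy), -1.0, 1.0))


def _pairwise_complete(X: np.ndarray, Y: np.ndarray, min_obs: int):
    """Vectorised pairwise-complete Pearson between rows of X and rows of Y.

    Returns (R, N) with R NaN where undefined.  Uses the moment identity
    over the shared-observation mask, which is exact for pairwise
    deletion.
    """
    MX = np.isfinite(X)
    MY = np.isfinite(Y)
    X0 = np.where(MX, X, 0.0)
    Y0 = np.where(MY, Y, 0.0)
    mx = MX.astype(float)
    my = MY.astype(float)
    N = mx @ my.T
    SX = X0 @ my.T          # sum of x over shared positions
    SY = (Y0 @ mx.T).T      # sum of y over shared positions
    SXX = (X0 * X0) @ my.T
    SYY = ((Y0 * Y0) @ mx.T).T
    SXY = X0 @ Y0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(N > 0, N, 1.0)
        cov = SXY - SX * SY / n
        vx = SXX - SX * SX / n
        vy = SYY - SY * SY / n
        R = cov / np.sqrt(vx * vy)
    undef = (N < min_obs) | (vx <= _VAR_EPS * n) | (vy <= _VAR_EPS * n)
    R = np.where(undef, np.nan, np.clip(R, -1.0, 1.0))
    return R, N.astype(int)


def _stacked(data: AlignedDataset):
    """Traits-then-transcripts variable matrix plus labels/classes."""
    ids = list(data.trait_ids) + list(data.transcript_ids)
    classes = {t: "trait" for t in data.trait_ids}
    classes.update({t: "transcript" for t in data.transcript_ids})
    values = np.vstack([data.phenotypes.values, data.expression.values])
    return ids, classes, values


def correlation_matrix(
    data: AlignedDataset,
    seeds: list[str] | None = None,
    min_obs: int = DEFAULT_MIN_OBS,
) -> CorrelationMatrix:
    """Pairwise Pearson correlations among traits and transcripts.

    With ``seeds`` given, only the seed rows are computed against all
    variables (the full transcript × transcript block stays NaN and is
    never materialised as dense sums) — use :func:`submatrix` afterwards
    to get all-pairs correlations among a chosen node subset.
    """
    ids, classes, values = _stacked(data)
    n = len(ids)
    if seeds is None:
        R, N = _pairwise_complete(values, values, min_obs)
    else:
        index = {node: i for i, node in enumerate(ids)}
        for s in seeds:
            if s not in index:
                raise UnknownNodeError(f"unknown seed {s!r}")
        rows = [index[s] for s in seeds]
        Rs, Ns = _pairwise_complete(values[rows], values, min_obs)
        R = np.full((n, n), np.nan)
        N = np.zeros((n, n), dtype=int)
        for k, i in enumerate(rows):
            R[i, :] = Rs[k]
            R[:, i] = Rs[k]
            N[i, :] = Ns[k]
            N[:, i] = Ns[k]
    return CorrelationMatrix(node_ids=ids, node_class=classes, r=R, n_obs=N)


def submatrix(
    data: AlignedDataset,
    nodes: list[str],
    min_obs: int = DEFAULT_MIN_OBS,
) -> CorrelationMatrix:
    """All-pairs correlation matrix restricted to ``nodes`` (order preserved
    as traits first then transcripts, each in the given relative order)."""
    ids, classes, values = _stacked(data)
    index = {node: i for i, node in enumerate(ids)}
    for node in nodes:
        if node not in index:
            raise UnknownNodeError(f"unknown node {node!r}")
    chosen = sorted(set(nodes), key=lambda node: index[node])
    rows = [index[node] for node in chosen]
    R, N = _pairwise_complete(values[rows], values[rows], min_obs)
    return CorrelationMatrix(
        node_ids=chosen,
        node_class={node: classes[node] for node in chosen},
        r=R,
        n_obs=N,
    )


def top_correlates(
    corr: CorrelationMatrix, seed_id: str, k: int | None = 20
) -> CorrelateTable:
    """Top-k correlates of a seed, descending r, ties broken lexically.

    The seed itself and undefined correlations are excluded.  ``k=None``
    returns every defined correlate.
    """
    i = corr._loc(seed_id)
    rows = [
        (node, float(corr.r[i, j]))
        for j, node in enumerate(corr.node_ids)
        if node != seed_id and np.isfinite(corr.r[i, j])
    ]
    rows.sort(key=lambda t: (-t[1], t[0]))
    if k is not None:
        rows = rows[:k]
    return CorrelateTable(seed_id=seed_id, rows=rows)


def correlate_frame(table: CorrelateTable) -> pd.DataFrame:
    """Ranked correlate table as a DataFrame (rank, node_id, r)."""
    return pd.DataFrame(
        [(rank, node, r) for rank, (node, r) in enumerate(table.rows, start=1)],
        columns=["rank", "node_id", "r"],
    )


def threshold_network(
    corr: CorrelationMatrix, tau: float, mode: str = "signed"
) -> Network:
    """Network of above-threshold correlations.

    Edge (i, j) exists iff r_ij is defined and r_ij >= tau (signed mode)
    or |r_ij| >= tau (absolute mode); the edge weight is r_ij.  All matrix
    nodes are kept, including isolated ones.  At tau = 0 (signed, all-
    positive r) the edge count reaches its (n² − n)/2 ceiling; at tau = 1
    only perfectly correlated distinct pairs — normally none — survive.
    """
    if not (-1.0 < tau <= 1.0):
        raise DomainError(f"tau must lie in (-1, 1], got {tau}")
    if mode not in ("signed", "absolute"):
        raise DomainError(f"unknown mode {mode!r}")
    net = Network()
    for node in corr.node_ids:
        net.add_node(node, corr.node_class.get(node, "transcript"))
    R = corr.r
    vals = np.abs(R) if mode == "absolute" else R
    n = len(corr.node_ids)
    iu, ju = np.triu_indices(n, k=1)
    keep = np.isfinite(R[iu, ju]) & (vals[iu, ju] >= tau)
    for i, j in zip(iu[keep], ju[keep]):
        net.add_edge(corr.node_ids[i], corr.node_ids[j], float(R[i, j]))
    return net


def seed_network(
    data: AlignedDataset,
    seeds: list[str],
    tau: float,
    mode: str = "signed",
    min_obs: int = DEFAULT_MIN_OBS,
) -> tuple[Network, CorrelationMatrix]:
    """Seed-restricted network: seeds, their above-threshold correlates, and
    all above-threshold edges among that union.

    This is the memory-frugal route for large transcriptomes: the full
    transcript × transcript matrix is never built, only seed rows plus
    the union-restricted block.
    """
    seed_corr = correlation_matrix(data, seeds=seeds, min_obs=min_obs)
    members: set[str] = set(seeds)
    for s in seeds:
        for node, r in top_correlates(seed_corr, s, k=None).rows:
            mag = abs(r) if mode == "absolute" else r
            if mag >= tau:
                members.add(node)
    corr = submatrix(data, sorted(members), min_obs=min_obs)
    log.info("seed_network: %d seeds -> %d member nodes", len(seeds), len(members))
    return threshold_network(corr, tau, mode), corr
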