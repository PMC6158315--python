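"""Degree distributions, log-log power-law fits, and threshold selection.

A network is called scale-free when its degree probability follows a
power law p(k) ∝ k^(−γ): a straight line in log-log coordinates.  The
fit here is ordinary least squares of log10 p on log10 k over the raw
(unbinned) empirical points — matching how such plots are usually read
by eye — and the coefficient of determination r² quantifies linearity.
Scanning candidate correlation thresholds and taking the smallest one
whose network fits well trades network size against scale-free topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import CorrelationMatrix, threshold_network
from .errors import (
    DegenerateDistributionError,
    DomainError,
    InsufficientPointsError,
    SelectionError,
)
from .graph import Network


@dataclass
class DegreeDistribution:
    """Empirical (degree k, probability p) pairs, zero-degree nodes excluded."""

    ks: np.ndarray  # distinct positive degrees, ascending
    ps: np.ndarray  # empirical probabilities, sum to 1


@dataclass
class ScaleFreeFit:
    """OLS fit of log10 p against log10 k."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    tau: float | None = None


@dataclass
class ScanRow:
    """One thresholded network's size and scale-free fit."""

    tau: float
    n_nodes: int
    n_edges: int
    n_points: int
    slope: float
    r_squared: float
    degenerate: bool


def degree_distribution(net: Network) -> DegreeDistribution:
    """Empirical degree distribution over nodes with degree >= 1.

    Zero-degree nodes are excluded from numerator and denominator (their
    log-degree is undefined), so the probabilities always sum to one.
    """
    degrees = np.array([net.degree(v) for v in net.nodes()], dtype=int)
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        raise DegenerateDistributionError("graph has no edges")
    ks, counts = np.unique(degrees, return_counts=True)
    return DegreeDistribution(ks=ks, ps=counts / degrees.size)


def loglog_fit(dist: DegreeDistribution, tau: float | None = None) -> ScaleFreeFit:
    """OLS of log10 p on log10 k; slope is the (negated) power-law exponent.

    With a constant p (zero total variance) the slope is 0 and r² is
    reported as 0.
    """
    if dist.ks.size < 3:
        raise InsufficientPointsError(
            f"log-log fit needs >= 3 distinct degrees, got {dist.ks.size}"
        )
    x = np.log10(dist.ks.astype(float))
    y = np.log10(dist.ps)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue) ** 2
    if not np.isfinite(r2):
        r2 = 0.0
    return ScaleFreeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=int(dist.ks.size),
        tau=tau,
    )


def threshold_scan(
    corr: CorrelationMatrix, taus, mode: str = "signed"
) -> list[ScanRow]:
    """Build the thresholded network at each tau and fit its degree
    distribution; edgeless or too-sparse-spectrum networks are flagged
    degenerate instead of aborting the scan."""
    rows: list[ScanRow] = []
    for tau in taus:
        if not (0.0 < tau < 1.0):
            raise DomainError(f"scan tau must lie in (0, 1), got {tau}")
        net = threshold_network(corr, tau, mode)
        try:
            fit = loglog_fit(degree_distribution(net), tau=tau)
        except (DegenerateDistributionError, InsufficientPointsError):
            rows.append(ScanRow(tau, net.n_nodes, net.n_edges, 0,
                                float("nan"), float("nan"), True))
            continue
        rows.append(ScanRow(tau, net.n_nodes, net.n_edges, fit.n_points,
                            fit.slope, fit.r_squared, False))
    return rows


def scan_frame(rows: list[ScanRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.tau, r.n_nodes, r.n_edges, r.n_points, r.slope, r.r_squared,
          int(r.degenerate)) for r in rows],
        columns=["tau", "n_nodes", "n_edges", "n_points", "slope",
                 "r_squared", "degenerate_flag"],
    )


def select_threshold(
    rows: list[ScanRow], r2_min: float = 0.8, min_points: int = 5
) -> float:
    """Smallest scanned tau whose fit is acceptably linear.

    Picking the *low* end of the well-fitting range keeps the network as
    large as possible while staying in the scale-free regime.
    """
    if not rows:
        raise SelectionError("empty threshold scan")
    best_r2 = -np.inf
    for row in sorted(rows, key=lambda r: r.tau):
        if row.degenerate:
            continue
        best_r2 = max(best_r2, row.r_squared)
        if row.r_squared >= r2_min and row.n_points >= min_points:
            return row.tau
    raise SelectionError(
        f"no threshold reached r^2 >= {r2_min} with >= {min_points} points "
        f"(best attained r^2 = {best_r2:.3f})"
    )
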