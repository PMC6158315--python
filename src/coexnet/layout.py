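"""Network layouts: simplified force-directed embedding and constrained-grid
stress minimisation, plus level colouring for percolation maps.

Both algorithms turn correlation into distance — strongly correlated
nodes end up close together — and both are deterministic for a fixed
seed.

* :func:`force_layout` places nodes in the plane and gradient-descends
  the squared mismatch between realised edge lengths and a per-edge
  target length (default 1 − r, so r = 1 wants coincident nodes).
* :func:`grid_layout` assigns each node to a distinct cell of an R × C
  grid, minimising a stress objective that compares normalised grid
  distance with normalised dissimilarity, by greedy seeded placement
  followed by simulated-annealing swaps.  Node pairs with no defined /
  above-threshold correlation get a dissimilarity cap larger than any
  connected pair's, which is what pushes unconnected nodes toward the
  periphery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .errors import CapacityError, DivergenceError, DomainError, UnknownNodeError
from .graph import UNREACHABLE, Network

#: dissimilarity assigned to unconnected / undefined pairs
D_MAX = 1.5


@dataclass
class ForceLayout:
    """Planar embedding: node → (x, y), with convergence diagnostics."""

    positions: dict[str, tuple[float, float]]
    n_iterations: int
    objective: float
    mean_edge_error: float


@dataclass
class GridLayout:
    """Injective node → (row, col) assignment on an R × C grid."""

    assignment: dict[str, tuple[int, int]]
    shape: tuple[int, int]
    objective: float


def default_target_length(weight: float) -> float:
    """Edge-length target 1 − r: perfect correlation wants distance 0."""
    return 1.0 - weight


def force_layout(
    net: Network,
    target_length=default_target_length,
    iterations: int = 500,
    step_size: float = 0.05,
    rng_seed: int = 0,
) -> ForceLayout:
    """Iteratively optimise edge distances by gradient descent.

    Minimises Σ_edges (‖p_u − p_v‖ − L(w_uv))² from seeded random
    positions in the unit square; stops early once an iteration improves
    the objective by less than 1e-9.
    """
    nodes = net.nodes()
    if not nodes:
        raise DomainError("force_layout needs at least one node")
    rng = np.random.default_rng(rng_seed)
    pos = rng.random((len(nodes), 2))
    index = {node: i for i, node in enumerate(nodes)}
    edges = net.edges()
    if not edges:
        return ForceLayout(
            positions={node: (float(x), float(y)) for node, (x, y) in zip(nodes, pos)},
            n_iterations=0, objective=0.0, mean_edge_error=0.0,
        )
    ui = np.array([index[u] for u, _, _ in edges])
    vi = np.array([index[v] for _, v, _ in edges])
    target = np.array([target_length(w) for _, _, w in edges], dtype=float)

    def objective_and_errors(p):
        with np.errstate(over="ignore", invalid="ignore"):
            diff = p[ui] - p[vi]
            dist = np.sqrt((diff * diff).sum(axis=1))
            err = dist - target
            return float(err @ err), dist, diff, err

    prev, dist, diff, err = objective_and_errors(pos)
    n_done = 0
    for n_done in range(1, iterations + 1):
        safe = np.where(dist < 1e-12, 1e-12, dist)
        # d objective / d p_u = 2 err * (p_u - p_v) / dist
        pull = (2.0 * err / safe)[:, None] * diff
        grad = np.zeros_like(pos)
        np.add.at(grad, ui, pull)
        np.add.at(grad, vi, -pull)
        pos = pos - step_size * grad
        obj, dist, diff, err = objective_and_errors(pos)
        if not math.isfinite(obj):
            raise DivergenceError(
                "force layout objective became non-finite; retry with a "
                "smaller step_size"
            )
        if 0.0 <= prev - obj < 1e-9:
            prev = obj
            break
        prev = obj
    return ForceLayout(
        positions={node: (float(x), float(y)) for node, (x, y) in zip(nodes, pos)},
        n_iterations=n_done,
        objective=prev,
        mean_edge_error=float(np.mean(np.abs(err))),
    )


# ---------------------------------------------------------------------------
# grid layout


def _dissimilarity_pairs(source, nodes, far_sample, rng):
    """Index pairs (i, j, normalised d) entering the grid objective.

    All pairs with d < D_MAX ("near": connected / defined correlation)
    are kept; each node additionally contributes a seeded sample of far
    pairs at the cap, which is what generates the outward pressure on
    unconnected nodes without an O(n²) objective.
    """
    index = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    near: dict[tuple[int, int], float] = {}
    if isinstance(source, Network):
        for u, v, w in source.edges():
            i, j = sorted((index[u], index[v]))
            near[(i, j)] = min(1.0 - w, D_MAX)
    elif isinstance(source, CorrelationMatrix):
        R = source.r
        iu, ju = np.triu_indices(n, k=1)
        finite = np.isfinite(R[iu, ju])
        for i, j in zip(iu[finite], ju[finite]):
            d = 1.0 - float(R[i, j])
            if d < D_MAX:
                near[(int(i), int(j))] = max(d, 0.0)
    else:
        raise DomainError(
            f"grid_layout needs a Network or CorrelationMatrix, got {type(source)!r}"
        )
    pairs = [(i, j, d / D_MAX) for (i, j), d in near.items()]
    near_set = set(near)
    if n > 1 and far_sample > 0:
        for i in range(n):
            k = min(far_sample, n - 1)
            for j in rng.choice(n - 1, size=k, replace=False):
                j = int(j) + (int(j) >= i)  # skip self
                a, b = (i, j) if i < j else (j, i)
                if (a, b) not in near_set:
                    near_set.add((a, b))
                    pairs.append((a, b, 1.0))
    return pairs


def grid_layout(
    source,
    grid_shape: tuple[int, int] | None = None,
    rng_seed: int = 0,
    moves: int = 20000,
    far_sample: int = 5,
    t0: float = 0.02,
    t_floor: float = 1e-6,
) -> GridLayout:
    """Arrange nodes on a constrained grid so distance reflects correlation.

    Objective: Σ over considered pairs (cell distance / grid diagonal −
    d / d_max)².  Optimisation: the most-connected node is placed at the
    grid centre, remaining nodes greedily at their best free cell in
    decreasing connectivity order, then ``moves`` simulated-annealing
    swap/relocation proposals with geometric cooling refine the
    assignment.  Returns the best assignment encountered, with the
    objective recomputed from scratch on it.
    """
    if isinstance(source, Network):
        nodes = source.nodes()
    elif isinstance(source, CorrelationMatrix):
        nodes = list(source.node_ids)
    else:
        raise DomainError(
            f"grid_layout needs a Network or CorrelationMatrix, got {type(source)!r}"
        )
    n = len(nodes)
    if n == 0:
        raise DomainError("grid_layout needs at least one node")
    if grid_shape is None:
        side = math.ceil(math.sqrt(n))
        grid_shape = (side, side)
    R, C = grid_shape
    if R * C < n:
        raise CapacityError(f"grid {R}x{C} cannot hold {n} nodes")
    rng = np.random.default_rng(rng_seed)
    pairs = _dissimilarity_pairs(source, nodes, far_sample, rng)
    diag = math.hypot(R - 1, C - 1) if R * C > 1 else 1.0

    # per-node partner arrays for incremental evaluation
    partners: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, d in pairs:
        partners[i].append((j, d))
        partners[j].append((i, d))
    part_idx = [np.array([p for p, _ in lst], dtype=int) for lst in partners]
    part_d = [np.array([d for _, d in lst]) for lst in partners]

    # --- greedy seeded placement -----------------------------------------
    conn = np.array([len(lst) for lst in partners])
    order = sorted(range(n), key=lambda i: (-conn[i], nodes[i]))
    cells = [(r, c) for r in range(R) for c in range(C)]
    cell_arr = np.array(cells, dtype=float)
    free = np.ones(len(cells), dtype=bool)
    pos = np.full((n, 2), -1.0)
    center = min(
        range(len(cells)),
        key=lambda k: (cell_arr[k, 0] - (R - 1) / 2) ** 2
        + (cell_arr[k, 1] - (C - 1) / 2) ** 2,
    )
    pos[order[0]] = cell_arr[center]
    free[center] = False
    placed = {order[0]}
    for node in order[1:]:
        mask = np.isin(part_idx[node], list(placed), assume_unique=False)
        free_cells = cell_arr[free]
        if mask.any():
            anchors = pos[part_idx[node][mask]]
            dn = part_d[node][mask]
            delta = free_cells[:, None, :] - anchors[None, :, :]
            dists = np.sqrt((delta * delta).sum(axis=2)) / diag
            cost = ((dists - dn[None, :]) ** 2).sum(axis=1)
            pick = int(np.argmin(cost))
        else:
            pick = 0
        cell_id = np.flatnonzero(free)[pick]
        pos[node] = cell_arr[cell_id]
        free[cell_id] = False
        placed.add(node)

    def node_cost(i, p, override=None):
        idx = part_idx[i]
        if idx.size == 0:
            return 0.0
        other = pos[idx].copy()
        if override is not None:
            j, pj = override
            hits = idx == j
            if hits.any():
                other[hits] = pj
        delta = other - p
        dists = np.sqrt((delta * delta).sum(axis=1)) / diag
        return float(((dists - part_d[i]) ** 2).sum())

    def total_objective():
        total = 0.0
        for i, j, d in pairs:
            delta = pos[i] - pos[j]
            dist = math.hypot(delta[0], delta[1]) / diag
            total += (dist - d) ** 2
        return total

    obj = total_objective()
    best_obj = obj
    best_pos = pos.copy()
    occupant = {tuple(map(int, pos[i])): i for i in range(n)}
    free_cells = [cell for cell in cells if cell not in occupant]
    cooling = (t_floor / t0) ** (1.0 / max(moves, 1)) if moves else 1.0
    temp = t0
    for _ in range(moves):
        i = int(rng.integers(n))
        if free_cells and rng.random() < 0.3:
            # relocate to a random empty cell
            kf = int(rng.integers(len(free_cells)))
            target = free_cells[kf]
            old_cell = tuple(map(int, pos[i]))
            new_p = np.array(target, dtype=float)
            delta_obj = node_cost(i, new_p) - node_cost(i, pos[i])
            if delta_obj < 0 or (
                temp > t_floor and rng.random() < math.exp(-delta_obj / temp)
            ):
                pos[i] = new_p
                occupant.pop(old_cell)
                occupant[target] = i
                free_cells[kf] = old_cell
                obj += delta_obj
        else:
            j = int(rng.integers(n))
            if i != j:
                pi, pj = pos[i].copy(), pos[j].copy()
                old = node_cost(i, pi) + node_cost(j, pj, override=(i, pi))
                new = node_cost(i, pj, override=(j, pi)) + node_cost(
                    j, pi, override=(i, pj)
                )
                delta_obj = new - old
                if delta_obj < 0 or (
                    temp > t_floor and rng.random() < math.exp(-delta_obj / temp)
                ):
                    pos[i], pos[j] = pj, pi
                    occupant[tuple(map(int, pi))] = j
                    occupant[tuple(map(int, pj))] = i
                    obj += delta_obj
        if obj < best_obj:
            best_obj = obj
            best_pos = pos.copy()
        temp = max(temp * cooling, t_floor)
    pos = best_pos
    final_obj = total_objective()
    assignment = {
        nodes[i]: (int(round(pos[i, 0])), int(round(pos[i, 1]))) for i in range(n)
    }
    if len(set(assignment.values())) != n:
        raise AssertionError("grid assignment lost injectivity")  # pragma: no cover
    return GridLayout(assignment=assignment, shape=(R, C), objective=final_obj)


def color_by_level(layout, levels: dict[str, float]) -> pd.DataFrame:
    """Join a layout with BFS levels into a render table.

    Columns: node_id, x, y, level, bucket.  Unreachable nodes go into
    the distinct "unconnected" bucket (drawn gray, pushed peripheral by
    the grid layout); the seed itself is bucket "0".
    """
    if isinstance(layout, ForceLayout):
        coords = layout.positions
    elif isinstance(layout, GridLayout):
        coords = {node: (float(r), float(c)) for node, (r, c) in layout.assignment.items()}
    else:
        raise DomainError(f"unsupported layout type {type(layout)!r}")
    if set(coords) != set(levels):
        missing = set(coords) ^ set(levels)
        raise UnknownNodeError(
            f"layout and level map disagree on nodes: {sorted(missing)[:5]}"
        )
    rows = []
    for node in sorted(coords):
        x, y = coords[node]
        level = levels[node]
        if level == UNREACHABLE:
            rows.append((node, x, y, float("inf"), "unconnected"))
        else:
            rows.append((node, x, y, float(level), str(int(level))))
    return pd.DataFrame(rows, columns=["node_id", "x", "y", "level", "bucket"])
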