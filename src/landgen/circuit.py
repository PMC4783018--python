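"""Circuit-theory connectivity: effective resistance and current maps.

The landscape is modeled as an electrical network: each non-nodata cell is a
node, each 8-neighbor pair a resistor whose conductance is the mean of the
two cells' conductances (1/resistance), divided by sqrt(2) on diagonals.
Current spread over all possible paths complements the single-route view of
least-cost paths; the "all-to-one" scheme grounds one focal element while
injecting unit current from every other, cycled over focals, and highlights
pinch points that concentrate flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, diags
from scipy.sparse.linalg import splu

from .raster import RasterError, RasterGrid, ResistanceSurface

SQRT2 = math.sqrt(2.0)


class CircuitError(ValueError):
    pass


@dataclass
class CircuitNetwork:
    """Conductance network over raster cells (optionally with merged focals).

    ``node_of_cell`` maps flat cell index -> network node (-1 for nodata);
    several cells may share a node after focal-patch contraction.
    """

    conductance: csr_matrix  # symmetric, zero diagonal, node x node
    node_of_cell: np.ndarray
    shape: tuple[int, int]
    tolerance: float = 1e-10

    @property
    def n_nodes(self) -> int:
        return self.conductance.shape[0]

    def laplacian(self) -> csr_matrix:
        deg = np.asarray(self.conductance.sum(axis=1)).ravel()
        return (diags(deg) - self.conductance).tocsr()


@dataclass
class CurrentMap:
    grid: RasterGrid  # per-cell current magnitude
    mode: str  # "all_to_one" | "pairwise"
    focal_spec: list


def build_network(surface: ResistanceSurface, tolerance: float = 1e-10) -> CircuitNetwork:
    """Conductance graph for a resistance surface.

    Edge conductance = mean(1/r_a, 1/r_b), divided by sqrt(2) for diagonal
    neighbors; nodata cells are excluded entirely.
    """
    grid = surface.grid
    ok = ~grid.nodata
    if not ok.any():
        raise CircuitError("all cells are nodata")
    nrows, ncols = grid.shape
    inv = np.zeros_like(grid.values)
    inv[ok] = 1.0 / grid.values[ok]
    node_of_cell = np.full(nrows * ncols, -1, dtype=int)
    node_of_cell[np.flatnonzero(ok.ravel())] = np.arange(int(ok.sum()))
    ii, jj, gg = [], [], []
    for dr, dc, diag in [(0, 1, False), (1, -1, True), (1, 0, False), (1, 1, True)]:
        r0s = slice(max(0, -dr), nrows - max(0, dr))
        c0s = slice(max(0, -dc), ncols - max(0, dc))
        r1s = slice(max(0, dr), nrows + min(0, dr))
        c1s = slice(max(0, dc), ncols + min(0, dc))
        both = ok[r0s, c0s] & ok[r1s, c1s]
        g = 0.5 * (inv[r0s, c0s] + inv[r1s, c1s])
        if diag:
            g = g / SQRT2
        rr, cc = np.nonzero(both)
        r0 = rr + r0s.start
        c0 = cc + c0s.start
        a = node_of_cell[r0 * ncols + c0]
        b = node_of_cell[(r0 + dr) * ncols + (c0 + dc)]
        ii.append(a)
        jj.append(b)
        gg.append(g[both])
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    g = np.concatenate(gg)
    n = int(ok.sum())
    cond = coo_matrix(
        (np.concatenate([g, g]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    return CircuitNetwork(cond, node_of_cell, (nrows, ncols), tolerance)


def contract_focal_patches(net: CircuitNetwork, patch_masks) -> tuple[CircuitNetwork, list[int]]:
    """Merge each patch's cells into a single super-node (infinite internal
    conductance), returning the new network and the focal node ids."""
    n = net.n_nodes
    group = np.arange(n)
    focal_nodes: list[int] = []
    next_id = 0
    assigned = np.full(n, -1, dtype=int)
    for mask in patch_masks:
        flat = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
        nodes = net.node_of_cell[flat]
        nodes = nodes[nodes >= 0]
        if nodes.size == 0:
            raise CircuitError("focal patch lies entirely on nodata")
        if np.any(assigned[nodes] >= 0):
            raise CircuitError("focal patches overlap")
        assigned[nodes] = len(focal_nodes)
        focal_nodes.append(-1)  # placeholder
    # relabel: patches first keep stable ids, then remaining nodes
    new_id = np.full(n, -1, dtype=int)
    n_patches = int(assigned.max()) + 1
    for p in range(n_patches):
        new_id[assigned == p] = p
    rest = np.flatnonzero(assigned < 0)
    new_id[rest] = n_patches + np.arange(rest.size)
    m = n_patches + rest.size
    c = net.conductance.tocoo()
    keep = new_id[c.row] != new_id[c.col]
    cond = coo_matrix(
        (c.data[keep], (new_id[c.row][keep], new_id[c.col][keep])), shape=(m, m)
    ).tocsr()
    cond.sum_duplicates()
    node_of_cell = net.node_of_cell.copy()
    valid = node_of_cell >= 0
    node_of_cell[valid] = new_id[node_of_cell[valid]]
    return (
        CircuitNetwork(cond, node_of_cell, net.shape, net.tolerance),
        list(range(n_patches)),
    )


def _components(net: CircuitNetwork) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(net.conductance, directed=False)
    return labels


def _solve_grounded(net: CircuitNetwork, ground: int, injection: np.ndarray) -> np.ndarray:
    """Node voltages with ``ground`` held at 0 V and ``injection`` (A) applied.

    Only the ground's connected component is solved; other components get
    voltage 0 (no current can reach them).  Direct sparse factorization is
    used throughout — desk-scale rasters (tens of thousands of nodes) solve
    in well under a second and the result is deterministic to solver
    tolerance.
    """
    labels = _components(net)
    comp = labels == labels[ground]
    if injection[~comp].any():
        raise CircuitError("injection outside the ground's connected component")
    idx = np.flatnonzero(comp)
    pos = np.searchsorted(idx, ground)
    L = net.laplacian()[np.ix_(idx, idx)].tocsc()
    keep = np.ones(idx.size, dtype=bool)
    keep[pos] = False
    Lr = L[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))]
    b = injection[idx][keep]
    v_r = splu(Lr.tocsc()).solve(b)
    v = np.zeros(net.n_nodes)
    vv = np.zeros(idx.size)
    vv[keep] = v_r
    v[idx] = vv
    return v


def effective_resistance(net: CircuitNetwork, a: int, b: int) -> float:
    """Two-point effective resistance; inf for disconnected nodes."""
    if a == b:
        return 0.0
    labels = _components(net)
    if labels[a] != labels[b]:
        return math.inf
    inj = np.zeros(net.n_nodes)
    inj[a] = 1.0
    inj[b] = -1.0
    v = _solve_grounded(net, b, inj)
    return float(v[a] - v[b])


def _branch_current_magnitude(net: CircuitNetwork, v: np.ndarray) -> np.ndarray:
    """Per-node current magnitude: half the sum of |I| over incident branches."""
    c = net.conductance.tocoo()
    flow = np.abs(v[c.row] - v[c.col]) * c.data
    out = np.zeros(net.n_nodes)
    np.add.at(out, c.row, flow)
    return 0.5 * out


def solve_all_to_one(
    net: CircuitNetwork, focal: list[int], template: RasterGrid | None = None,
) -> CurrentMap:
    """Accumulated current magnitude over the all-to-one solve cycle.

    Each focal element in turn is grounded while unit current is injected at
    every other focal element; per-cell current magnitudes (half-sum of
    absolute incident branch currents) are summed over solves.
    """
    focal = list(focal)
    if len(focal) < 2:
        raise CircuitError("need at least 2 focal elements")
    labels = _components(net)
    total = np.zeros(net.n_nodes)
    for ground in focal:
        inj = np.zeros(net.n_nodes)
        reachable = [f for f in focal if f != ground and labels[f] == labels[ground]]
        if not reachable:
            continue
        for f in reachable:
            inj[f] = 1.0
        v = _solve_grounded(net, ground, inj)
        total += _branch_current_magnitude(net, v)
    # paint back to cells (merged focal nodes paint all their cells)
    nrows, ncols = net.shape
    cell_current = np.zeros(nrows * ncols)
    valid = net.node_of_cell >= 0
    cell_current[valid] = total[net.node_of_cell[valid]]
    grid_vals = cell_current.reshape(nrows, ncols)
    if template is not None:
        grid = RasterGrid(grid_vals, template.cell_size, template.origin_x,
                          template.origin_y, template.nodata.copy())
    else:
        grid = RasterGrid(grid_vals, 1.0)
    return CurrentMap(grid, "all_to_one", focal)


def node_of_point(net: CircuitNetwork, row: int, col: int) -> int:
    node = int(net.node_of_cell[row * net.shape[1] + col])
    if node < 0:
        raise CircuitError(f"cell ({row}, {col}) is nodata")
    return node
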