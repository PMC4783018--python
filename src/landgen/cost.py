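"""Cost-distance matrices and least-cost paths on resistance surfaces.

Movement is modeled on the 8-connected cell graph.  Each move between
adjacent cells costs the mean of the two cells' resistances, scaled by sqrt(2)
for diagonal moves — the standard GIS cost-distance semantics.  Cumulative
cost along the cheapest route between two sampling locations is the
"effective distance" fed to the Mantel and mixed-model machinery; costs are
in resistance x cell-lengths (the global cell-size factor is immaterial to
every downstream correlation or fit).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .genetics import DistanceMatrix
from .raster import RasterError, ResistanceSurface

SQRT2 = math.sqrt(2.0)

#: (dr, dc, diagonal?) for the 8 neighbors.
NEIGHBORS = [
    (-1, -1, True), (-1, 0, False), (-1, 1, True),
    (0, -1, False), (0, 1, False),
    (1, -1, True), (1, 0, False), (1, 1, True),
]


@dataclass
class CostDistanceResult:
    distances: DistanceMatrix  # kind="effective"
    paths: dict | None = None  # (i, j) -> list of (row, col)
    surface_id: str | None = None


def surface_graph(surface: ResistanceSurface):
    """Sparse symmetric 8-connectivity cost graph over non-nodata cells.

    Returns (csr_matrix over flat cell indices, flat index array of valid
    cells).  Nodata cells have no incident edges (impassable).
    """
    grid = surface.grid
    vals = grid.values
    ok = ~grid.nodata
    if vals[ok].size and vals[ok].min() < 1:
        raise RasterError("resistance values must be >= 1")
    nrows, ncols = grid.shape
    rows_i, cols_j, weights = [], [], []
    # only forward neighbors to build each undirected edge once
    for dr, dc, diag in [(0, 1, False), (1, -1, True), (1, 0, False), (1, 1, True)]:
        r0s = slice(max(0, -dr), nrows - max(0, dr))
        c0s = slice(max(0, -dc), ncols - max(0, dc))
        r1s = slice(max(0, dr), nrows + min(0, dr))
        c1s = slice(max(0, dc), ncols + min(0, dc))
        a_ok = ok[r0s, c0s] & ok[r1s, c1s]
        w = 0.5 * (vals[r0s, c0s] + vals[r1s, c1s])
        if diag:
            w = w * SQRT2
        rr, cc = np.nonzero(a_ok)
        r0 = rr + r0s.start
        c0 = cc + c0s.start
        rows_i.append(r0 * ncols + c0)
        cols_j.append((r0 + dr) * ncols + (c0 + dc))
        weights.append(w[a_ok])
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_j)
    w = np.concatenate(weights)
    n = nrows * ncols
    m = coo_matrix((np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
                   shape=(n, n)).tocsr()
    return m, np.flatnonzero(ok.ravel())


def _check_points(surface: ResistanceSurface, points) -> np.ndarray:
    grid = surface.grid
    pts = []
    for p in points:
        r, c = int(p[0]), int(p[1])
        if not (0 <= r < grid.nrows and 0 <= c < grid.ncols):
            raise RasterError(f"point ({r}, {c}) outside grid")
        if grid.nodata[r, c]:
            raise RasterError(f"point ({r}, {c}) lies on a nodata cell")
        pts.append(r * grid.ncols + c)
    return np.asarray(pts, dtype=int)


def cost_distance_matrix(
    surface: ResistanceSurface, points, labels=None, return_paths: bool = False,
) -> CostDistanceResult:
    """All-pairs least-cost distances between snapped sampling cells.

    ``points`` is a sequence of (row, col).  Disconnected pairs are recorded
    as +inf.  Units: resistance x cell lengths.
    """
    flat = _check_points(surface, points)
    graph, _ = surface_graph(surface)
    dist = dijkstra(graph, directed=False, indices=flat)
    sub = dist[:, flat]
    sub = 0.5 * (sub + sub.T)  # symmetric up to float round-off
    np.fill_diagonal(sub, 0.0)
    if labels is None:
        labels = [f"p{k}" for k in range(len(flat))]
    dm = DistanceMatrix(list(labels), sub, "effective")
    paths = None
    if return_paths:
        paths = {}
        ncols = surface.grid.ncols
        for a in range(len(flat)):
            for b in range(a + 1, len(flat)):
                p, _ = least_cost_path(
                    surface,
                    divmod(int(flat[a]), ncols),
                    divmod(int(flat[b]), ncols),
                    _graph=graph,
                )
                paths[(a, b)] = p
    return CostDistanceResult(dm, paths)


def least_cost_path(surface: ResistanceSurface, a, b, _graph=None):
    """One minimal-cost cell path from a to b, plus its cumulative cost.

    Ties among equal-cost paths are broken deterministically by preferring the
    lexicographically smallest predecessor cell index during backtracking, so
    corridors are reproducible across runs and platforms.  Returns
    ``(None, inf)`` when b is unreachable from a.
    """
    flat = _check_points(surface, [a, b])
    graph = _graph if _graph is not None else surface_graph(surface)[0]
    dist = dijkstra(graph, directed=False, indices=flat[0])
    total = float(dist[flat[1]])
    if not np.isfinite(total):
        return None, math.inf
    ncols = surface.grid.ncols
    nrows = surface.grid.nrows
    vals = surface.grid.values
    nodata = surface.grid.nodata
    # walk back from b choosing, among neighbors on a shortest path, the
    # smallest flat index
    path = [int(flat[1])]
    cur = int(flat[1])
    tol = 1e-9 * max(1.0, total)
    while cur != int(flat[0]):
        r, c = divmod(cur, ncols)
        best = None
        for dr, dc, diag in NEIGHBORS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrows and 0 <= cc < ncols) or nodata[rr, cc]:
                continue
            w = 0.5 * (vals[r, c] + vals[rr, cc]) * (SQRT2 if diag else 1.0)
            nb = rr * ncols + cc
            if abs(dist[nb] + w - dist[cur]) <= tol:
                if best is None or nb < best:
                    best = nb
        if best is None:  # pragma: no cover - defensive
            raise RuntimeError("path backtracking failed")
        path.append(best)
        cur = best
    path.reverse()
    cells = [divmod(p, ncols) for p in path]
    return cells, total


def paths_to_count_raster(surface: ResistanceSurface, paths: dict) -> np.ndarray:
    """Per-cell count of least-cost paths traversing the cell."""
    count = np.zeros(surface.grid.shape, dtype=int)
    for p in paths.values():
        if p is None:
            continue
        for r, c in p:
            count[r, c] += 1
    return count


def path_to_geojson(surface: ResistanceSurface, cells, properties=None) -> dict:
    """GeoJSON LineString through the traversed cell centers."""
    coords = [list(surface.grid.cell_center(r, c)) for r, c in cells]
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": properties or {},
    }


def write_paths_geojson(surface: ResistanceSurface, paths: dict, path) -> None:
    features = [
        path_to_geojson(surface, cells, {"pair": f"{i}-{j}"})
        for (i, j), cells in sorted(paths.items())
        if cells is not None
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
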