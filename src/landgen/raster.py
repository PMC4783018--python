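"""Raster data model, feature layers, and resistance-surface construction.

The analysis operates on square-celled rasters in a single projected CRS
(meters).  A landcover map is decomposed into binary feature layers (forest,
development, road classes 1-6, wetland types, ...), each of which can be
turned into a resistance surface either alone (univariate) or combined with
others (multivariate), with roads optionally modeled as simultaneous
barriers (the carriageway) and facilitators (a one-cell roadside strip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Sanctioned barrier resistance values tested against a background of 1.
BARRIER_VALUE_GRID = (2, 5, 10, 25, 50, 100, 250, 500, 750, 1000)

#: Background resistance assigned off-feature in facilitator mode.
FACILITATOR_BACKGROUND = 100.0

#: Feature names that may act as both barrier and facilitator.
DUAL_ROLE_FEATURES = frozenset(
    {
        "fields",
        "forested_wetland",
        "scrub_shrub_wetland",
        "palustrine_emergent_wetland",
        "estuarine_emergent_wetland",
    }
)

ROAD_CLASSES = (1, 2, 3, 4, 5, 6)


class RasterError(ValueError):
    """Raised for invalid raster inputs or out-of-bounds geometry."""


@dataclass
class RasterGrid:
    """Rectangular grid of cell values with georeferencing.

    Rows are 0-based and run top-to-bottom; ``origin_x``/``origin_y`` are the
    projected coordinates of the lower-left corner (ESRI ASCII convention).
    ``nodata`` is a boolean mask of excluded (impassable) cells.
    """

    values: np.ndarray
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise RasterError("cell_size must be positive")
        if self.nodata is None:
            self.nodata = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.values.shape:
                raise RasterError("nodata mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata])):
            raise RasterError("non-nodata cells must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected coordinates of the center of cell (row, col)."""
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def snap(self, x: float, y: float) -> tuple[int, int]:
        """Nearest cell (row, col) for a projected point; must lie in bounds."""
        col = int(math.floor((x - self.origin_x) / self.cell_size))
        row = int(math.floor((self.origin_y + self.nrows * self.cell_size - y) / self.cell_size))
        # points exactly on the top/right edge belong to the edge cell
        col = min(max(col, 0), self.ncols - 1) if self._inside(x, y) else col
        row = min(max(row, 0), self.nrows - 1) if self._inside(x, y) else row
        if not self._inside(x, y):
            raise RasterError(f"point ({x}, {y}) outside raster bounds")
        return row, col

    def _inside(self, x: float, y: float) -> bool:
        return (
            self.origin_x <= x <= self.origin_x + self.ncols * self.cell_size
            and self.origin_y <= y <= self.origin_y + self.nrows * self.cell_size
        )

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.values.copy(), self.cell_size, self.origin_x, self.origin_y, self.nodata.copy()
        )

    # -- ESRI ASCII grid I/O ------------------------------------------------

    def write_ascii(self, path, nodata_value: float = -9999.0) -> None:
        vals = self.values.copy()
        vals[self.nodata] = nodata_value
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.origin_x}\n")
            fh.write(f"yllcorner {self.origin_y}\n")
            fh.write(f"cellsize {self.cell_size}\n")
            fh.write(f"NODATA_value {nodata_value}\n")
            for row in vals:
                fh.write(" ".join(format(v, ".10g") for v in row) + "\n")

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                    header[key] = float(parts[1])
                else:
                    rows.append([float(p) for p in parts])
        values = np.array(rows, dtype=float)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise RasterError("ASCII grid body does not match declared shape")
        nodata_value = header.get("nodata_value", -9999.0)
        nodata = values == nodata_value
        values = np.where(nodata, 1.0, values)
        return cls(values, header["cellsize"], header["xllcorner"], header["yllcorner"], nodata)


@dataclass
class FeatureLayer:
    """Binary presence mask for one landscape feature with its movement role."""

    name: str
    mask: RasterGrid
    role: str  # "barrier", "facilitator", or "both"

    def __post_init__(self) -> None:
        if self.role not in {"barrier", "facilitator", "both"}:
            raise RasterError(f"unknown feature role {self.role!r}")
        m = self.mask.values
        if not np.all((m == 0) | (m == 1)):
            raise RasterError("feature mask values must be 0 or 1")

    @property
    def cells(self) -> np.ndarray:
        return self.mask.values.astype(bool)


@dataclass
class ResistanceSurface:
    """Raster of per-cell movement resistance with per-feature provenance."""

    grid: RasterGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.grid.values[~self.grid.nodata]
        if vals.size and vals.min() < 1:
            raise RasterError("resistance values must be >= 1 on non-nodata cells")


# ---------------------------------------------------------------------------
# Polyline rasterization (supercover tracing)
# ---------------------------------------------------------------------------


def _supercover_cells(x0, y0, x1, y1, nrows, ncols, cell_size, origin_x, origin_y):
    """All (row, col) whose cell square is intersected by the segment.

    Works in fractional cell coordinates with x right / y down so that row =
    floor(y), col = floor(x).  A corner crossing marks both diagonal cells,
    which prevents diagonal leaks through one-cell-wide linear features.
    """
    top = origin_y + nrows * cell_size
    fx0 = (x0 - origin_x) / cell_size
    fy0 = (top - y0) / cell_size
    fx1 = (x1 - origin_x) / cell_size
    fy1 = (top - y1) / cell_size

    cells: set[tuple[int, int]] = set()

    def clamp(i, n):
        return min(max(i, 0), n - 1)

    def mark(fx, fy):
        cells.add((clamp(int(math.floor(fy)), nrows), clamp(int(math.floor(fx)), ncols)))

    # collect every parameter value where the segment crosses a grid line
    dx, dy = fx1 - fx0, fy1 - fy0
    ts = [0.0, 1.0]
    if dx != 0:
        step = 1 if dx > 0 else -1
        c = math.floor(fx0) + (1 if dx > 0 else 0)
        while (c - fx0) / dx <= 1:
            t = (c - fx0) / dx
            if 0 < t < 1:
                ts.append(t)
            c += step
            if len(ts) > 10000:  # pragma: no cover - guard
                break
    if dy != 0:
        step = 1 if dy > 0 else -1
        c = math.floor(fy0) + (1 if dy > 0 else 0)
        while (c - fy0) / dy <= 1:
            t = (c - fy0) / dy
            if 0 < t < 1:
                ts.append(t)
            c += step
            if len(ts) > 20000:  # pragma: no cover - guard
                break
    ts = sorted(set(ts))
    # midpoint of each sub-interval lies strictly inside one cell
    for a, b in zip(ts[:-1], ts[1:]):
        tm = (a + b) / 2
        mark(fx0 + tm * dx, fy0 + tm * dy)
    # corner/grid-line touches: mark all cells adjacent to the crossing point
    eps = 1e-9
    for t in ts:
        px, py = fx0 + t * dx, fy0 + t * dy
        on_x = abs(px - round(px)) < eps
        on_y = abs(py - round(py)) < eps
        if on_x and on_y:
            cx, cy = round(px), round(py)
            for rr in (cy - 1, cy):
                for cc in (cx - 1, cx):
                    if 0 <= rr < nrows and 0 <= cc < ncols:
                        cells.add((int(rr), int(cc)))
    return cells


def rasterize_polyline(
    path_vertices, grid_template: RasterGrid, width_cells: int = 1, name: str = "line",
    role: str = "barrier",
) -> FeatureLayer:
    """Trace a projected polyline onto the grid as a binary feature mask.

    Supercover tracing: every cell whose square the line touches is marked, so
    the traced path is connected under 8-connectivity with no diagonal gaps.
    ``width_cells`` of 2 dilates the trace by one cell perpendicular to the
    dominant orientation of each segment (used for multi-lane highways whose
    true width is two cells).
    """
    verts = list(path_vertices)
    if not verts:
        raise RasterError("empty vertex list")
    if width_cells not in (1, 2):
        raise RasterError("width_cells must be 1 or 2")
    g = grid_template
    for v in verts:
        if not g._inside(v[0], v[1]):
            raise RasterError(f"vertex {v} outside grid")
    mask = np.zeros(g.shape, dtype=float)
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        seg = _supercover_cells(x0, y0, x1, y1, g.nrows, g.ncols, g.cell_size, g.origin_x, g.origin_y)
        for r, c in seg:
            mask[r, c] = 1.0
        if width_cells == 2:
            horiz = abs(x1 - x0) >= abs(y1 - y0)
            for r, c in seg:
                rr, cc = (r + 1, c) if horiz else (r, c + 1)
                if 0 <= rr < g.nrows and 0 <= cc < g.ncols:
                    mask[rr, cc] = 1.0
    if len(verts) == 1:
        r, c = g.snap(*verts[0])
        mask[r, c] = 1.0
    layer_grid = RasterGrid(mask, g.cell_size, g.origin_x, g.origin_y, g.nodata.copy())
    return FeatureLayer(name=name, mask=layer_grid, role=role)


# ---------------------------------------------------------------------------
# Surface construction
# ---------------------------------------------------------------------------


def build_univariate_surface(
    feature: FeatureLayer,
    mode: str,
    value: float = 1.0,
    value_grid=BARRIER_VALUE_GRID,
) -> ResistanceSurface:
    """Binary friction grid for one feature.

    Barrier mode assigns ``value`` (from the sanctioned grid) to feature cells
    against a background of 1; facilitator mode assigns 1 to feature cells
    against a background of 100.
    """
    g = feature.mask
    if mode == "barrier":
        if value_grid is not None and value not in value_grid:
            raise RasterError(f"barrier value {value} not in sanctioned grid {tuple(value_grid)}")
        vals = np.where(feature.cells, float(value), 1.0)
        prov = {feature.name: ("barrier", float(value))}
    elif mode == "facilitator":
        if value != 1:
            raise RasterError("facilitator mode requires value 1")
        vals = np.where(feature.cells, 1.0, FACILITATOR_BACKGROUND)
        prov = {feature.name: ("facilitator", 1.0)}
    else:
        raise RasterError(f"unknown mode {mode!r}")
    grid = RasterGrid(vals, g.cell_size, g.origin_x, g.origin_y, g.nodata.copy())
    return ResistanceSurface(grid, prov)


def _dilate8(mask: np.ndarray) -> np.ndarray:
    """8-neighborhood binary dilation (one cell)."""
    out = mask.copy()
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    out[1:, 1:] |= mask[:-1, :-1]
    out[1:, :-1] |= mask[:-1, 1:]
    out[:-1, 1:] |= mask[1:, :-1]
    out[:-1, :-1] |= mask[1:, 1:]
    return out


def build_buffered_road_surface(
    road_layers: dict[int, FeatureLayer],
    barrier_values: dict[int, float],
    buffered_classes=frozenset(),
) -> ResistanceSurface:
    """Roads as simultaneous barriers and roadside facilitators.

    Road cells carry their class's optimized barrier value (on overlap the
    largest resistance wins).  For each class in ``buffered_classes`` the
    cells 8-adjacent to that class's carriageway — excluding cells that are
    themselves road of any class — are set to 1, modeling the shrubby
    right-of-way strip that runs parallel to the road.
    """
    if not road_layers:
        raise RasterError("no road layers supplied")
    classes = sorted(road_layers)
    if not set(classes) <= set(ROAD_CLASSES):
        raise RasterError(f"road classes must be within {ROAD_CLASSES}")
    template = road_layers[classes[0]].mask
    vals = np.ones(template.shape, dtype=float)
    any_road = np.zeros(template.shape, dtype=bool)
    prov: dict = {}
    for cls in classes:
        layer = road_layers[cls]
        bv = float(barrier_values[cls])
        cells = layer.cells
        vals[cells] = np.maximum(vals[cells], bv)
        any_road |= cells
        prov[f"road_class_{cls}"] = ("barrier", bv)
    for cls in sorted(set(buffered_classes)):
        if cls not in road_layers:
            continue
        buf = _dilate8(road_layers[cls].cells) & ~any_road
        vals[buf] = 1.0
        prov[f"road_class_{cls}_buffer"] = ("facilitator", 1.0)
    grid = RasterGrid(vals, template.cell_size, template.origin_x, template.origin_y,
                      template.nodata.copy())
    return ResistanceSurface(grid, prov)


#: Multivariate model presets: which features enter, and in which role.
#: "roadsides" refers to the roadside facilitator strips of the buffered-road
#: construction; road carriageways are barriers wherever roads are included.
MODEL_PRESETS = {
    "all_barriers": {
        "barriers": ["forest", "forested_wetland", "estuarine_emergent_wetland",
                     "water", "fields", "development", "roads"],
        "facilitators": [],
    },
    "natural_barriers": {
        "barriers": ["forested_wetland", "estuarine_emergent_wetland", "water", "fields"],
        "facilitators": [],
    },
    "natural_facilitators": {
        "barriers": [],
        "facilitators": ["palustrine_emergent_wetland", "scrub_shrub_wetland",
                         "scrub_shrub", "lidar_veg"],
    },
    "all_facilitators": {
        "barriers": [],
        "facilitators": ["palustrine_emergent_wetland", "scrub_shrub_wetland", "scrub_shrub",
                         "powerline", "railroad", "roadsides", "lidar_veg"],
    },
    "linear_facilitators": {
        "barriers": [],
        "facilitators": ["powerline", "railroad", "roadsides"],
    },
    "landcover": {
        "barriers": ["forest", "development", "water", "fields",
                     "forested_wetland", "estuarine_emergent_wetland"],
        "facilitators": ["scrub_shrub", "scrub_shrub_wetland", "palustrine_emergent_wetland"],
    },
    "development_roads": {
        "barriers": ["development", "roads"],
        "facilitators": [],
    },
    "global": {
        "barriers": ["forest", "forested_wetland", "estuarine_emergent_wetland", "water",
                     "fields", "development", "roads"],
        "facilitators": ["palustrine_emergent_wetland", "scrub_shrub_wetland", "scrub_shrub",
                         "powerline", "railroad", "roadsides", "lidar_veg"],
    },
}


def compose_multivariate_surface(features, road_spec=None) -> ResistanceSurface:
    """Combine optimized univariate features into one resistance surface.

    ``features`` is a list of ``(FeatureLayer, role, value)`` with role
    already resolved to "barrier" or "facilitator".  Precedence is
    deterministic: barriers combine cellwise by maximum over a background of
    1; facilitators then set their cells to 1 except on road carriageway
    cells; road buffers (from ``road_spec``) are applied last.

    ``road_spec`` is ``(road_layers, barrier_values, buffered_classes)`` as
    for :func:`build_buffered_road_surface`, or None.
    """
    template = None
    for layer, role, _ in features:
        if role not in {"barrier", "facilitator"}:
            raise RasterError(
                f"feature {layer.name!r} has unresolved role {role!r}; resolve 'both' first"
            )
        template = template or layer.mask
    road_layers: dict[int, FeatureLayer] = {}
    barrier_values: dict[int, float] = {}
    buffered_classes: frozenset = frozenset()
    if road_spec is not None:
        road_layers, barrier_values, buffered_classes = road_spec
        road_layers = dict(road_layers)
        if template is None and road_layers:
            template = next(iter(road_layers.values())).mask
    if template is None:
        raise RasterError("no features supplied")

    vals = np.ones(template.shape, dtype=float)
    prov: dict = {}
    any_road = np.zeros(template.shape, dtype=bool)
    for cls, layer in sorted(road_layers.items()):
        cells = layer.cells
        bv = float(barrier_values[cls])
        vals[cells] = np.maximum(vals[cells], bv)
        any_road |= cells
        prov[f"road_class_{cls}"] = ("barrier", bv)
    for layer, role, value in features:
        if role == "barrier":
            cells = layer.cells
            vals[cells] = np.maximum(vals[cells], float(value))
            prov[layer.name] = ("barrier", float(value))
    for layer, role, value in features:
        if role == "facilitator":
            cells = layer.cells & ~any_road
            vals[cells] = 1.0
            prov[layer.name] = ("facilitator", 1.0)
    for cls in sorted(set(buffered_classes)):
        if cls not in road_layers:
            continue
        buf = _dilate8(road_layers[cls].cells) & ~any_road
        vals[buf] = 1.0
        prov[f"road_class_{cls}_buffer"] = ("facilitator", 1.0)
    grid = RasterGrid(vals, template.cell_size, template.origin_x, template.origin_y,
                      template.nodata.copy())
    return ResistanceSurface(grid, prov)
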