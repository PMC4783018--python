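"""Synthetic landscapes, sampling designs, and genotypes.

Two study areas with contrasting composition are emulated: a "Kittery-like"
rural landscape dominated by forest with a dense road network, and a "Cape
Elizabeth-like" suburban landscape with more development and estuarine
wetland.  Landcover classes are grown as blob-shaped patches at configurable
proportions on a ~30 m grid; linear anthropogenic features (six road
classes, a powerline, a railroad) are polylines rasterized onto the grid,
and an optional short-stature-vegetation speckle layer covers ~1% of cells,
emulating a LiDAR-derived 1-3 m vegetation mask.

Genotypes come from two generators.  The fast pairwise generator writes
genetic distances directly as a linear function of cost distance through a
known "true" resistance surface plus noise with the shared-individual
correlation structure of the MLPE model — exact statistical control for
optimizer and model-selection tests.  The mechanistic forward generator runs
a finite-island, stepwise-mutation microsatellite simulation with migration
decaying in cost distance — biological plausibility for end-to-end recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import DistanceMatrix, GenotypeTable
from .raster import FeatureLayer, RasterGrid, rasterize_polyline

#: Landcover composition defaults per study area (proportion of cells).
KITTERY_LIKE = {
    "development": 0.112,
    "fields": 0.111,
    "scrub_shrub": 0.046,
    "forested_wetland": 0.074,
    "scrub_shrub_wetland": 0.015,
    "palustrine_emergent_wetland": 0.010,
    "estuarine_emergent_wetland": 0.010,
    "water": 0.033,
    # remainder (0.588) = forest background
}

CAPE_LIKE = {
    "development": 0.286,
    "fields": 0.089,
    "scrub_shrub": 0.039,
    "forested_wetland": 0.093,
    "scrub_shrub_wetland": 0.011,
    "palustrine_emergent_wetland": 0.021,
    "estuarine_emergent_wetland": 0.092,
    "water": 0.031,
    # remainder (0.339 + road overlap) = forest background
}

#: Road classes present per emulated area: the suburban area lacks multi-lane
#: highways (class 1-2) and unmaintained roads (class 6).
KITTERY_ROAD_CLASSES = (1, 2, 3, 4, 5, 6)
CAPE_ROAD_CLASSES = (3, 4, 5)

FACILITATOR_FEATURES = {"scrub_shrub", "scrub_shrub_wetland",
                        "palustrine_emergent_wetland", "lidar_veg"}

LIDAR_COVER = 0.01  # fraction of cells in the vegetation speckle layer


class SynthError(ValueError):
    pass


@dataclass
class SyntheticLandscape:
    template: RasterGrid
    landcover: dict[str, FeatureLayer]           # mutually exclusive classes
    road_layers: dict[int, FeatureLayer]         # class -> layer (overlay)
    linear_layers: dict[str, FeatureLayer]       # powerline, railroad
    lidar_veg: FeatureLayer | None
    seed: int

    def all_layers(self) -> dict[str, FeatureLayer]:
        out = dict(self.landcover)
        for cls, layer in self.road_layers.items():
            out[f"road_class_{cls}"] = layer
        out.update(self.linear_layers)
        if self.lidar_veg is not None:
            out["lidar_veg"] = self.lidar_veg
        return out

    def roads_combined(self) -> FeatureLayer:
        mask = np.zeros(self.template.shape)
        for layer in self.road_layers.values():
            mask = np.maximum(mask, layer.mask.values)
        g = self.template
        return FeatureLayer(
            "roads", RasterGrid(mask, g.cell_size, g.origin_x, g.origin_y, g.nodata.copy()),
            "barrier",
        )


def _grow_blobs(assigned: np.ndarray, target: int, class_id: int, rng,
                mean_blob: int = 60) -> None:
    """Seeded random region growth of ~mean_blob-cell patches into free cells.

    ``assigned`` holds 0 for free (background) cells; grown cells are set to
    ``class_id`` in place until ``target`` cells are claimed.
    """
    nrows, ncols = assigned.shape
    grown = 0
    guard = 0
    while grown < target and guard < 10000:
        guard += 1
        free = np.flatnonzero(assigned.ravel() == 0)
        if free.size == 0:
            break
        start = int(free[rng.integers(free.size)])
        blob_target = min(target - grown, max(1, int(rng.poisson(mean_blob))))
        frontier = [start]
        assigned.ravel()[start] = class_id
        grown += 1
        blob = 1
        while frontier and blob < blob_target:
            k = int(rng.integers(len(frontier)))
            cell = frontier[k]
            r, c = divmod(cell, ncols)
            nbrs = []
            if r > 0:
                nbrs.append(cell - ncols)
            if r < nrows - 1:
                nbrs.append(cell + ncols)
            if c > 0:
                nbrs.append(cell - 1)
            if c < ncols - 1:
                nbrs.append(cell + 1)
            free_nbrs = [nb for nb in nbrs if assigned.ravel()[nb] == 0]
            if not free_nbrs:
                frontier.pop(k)
                continue
            nb = free_nbrs[int(rng.integers(len(free_nbrs)))]
            assigned.ravel()[nb] = class_id
            frontier.append(nb)
            grown += 1
            blob += 1
            if grown >= target:
                break


def _random_crossing_line(g: RasterGrid, rng) -> list[tuple[float, float]]:
    """A gently-bent polyline entering one grid edge and leaving the opposite."""
    w = g.ncols * g.cell_size
    h = g.nrows * g.cell_size
    x0, y0 = g.origin_x, g.origin_y
    if rng.random() < 0.5:  # left-right
        ya = y0 + rng.uniform(0.1, 0.9) * h
        yb = y0 + rng.uniform(0.1, 0.9) * h
        mid = (x0 + 0.5 * w, 0.5 * (ya + yb) + rng.uniform(-0.1, 0.1) * h)
        return [(x0 + 1e-6, ya), mid, (x0 + w - 1e-6, yb)]
    xa = x0 + rng.uniform(0.1, 0.9) * w
    xb = x0 + rng.uniform(0.1, 0.9) * w
    mid = (0.5 * (xa + xb) + rng.uniform(-0.1, 0.1) * w, y0 + 0.5 * h)
    return [(xa, y0 + 1e-6), mid, (xb, y0 + h - 1e-6)]


def generate_landscape(
    composition: dict[str, float] | None = None,
    shape: tuple[int, int] = (200, 200),
    cell_size: float = 30.0,
    road_classes=KITTERY_ROAD_CLASSES,
    roads_per_class: int = 1,
    include_lidar: bool = False,
    seed: int = 0,
) -> SyntheticLandscape:
    """Generate one study-area landscape.

    ``composition`` maps landcover class to its target cell proportion (the
    remainder is forest); defaults to the rural profile.  Roads, powerline
    and railroad are overlay layers (they coexist with landcover classes, as
    in the source GIS layers); the class-1 highway is two cells wide.
    """
    composition = dict(KITTERY_LIKE if composition is None else composition)
    total = sum(composition.values())
    if total > 1.0 + 1e-9:
        raise SynthError(f"class proportions sum to {total:.3f} > 1")
    rng = np.random.default_rng(seed)
    nrows, ncols = shape
    template = RasterGrid(np.ones(shape), cell_size)
    assigned = np.zeros(shape, dtype=int)
    names = sorted(composition)  # deterministic order
    for k, name in enumerate(names, start=1):
        target = int(round(composition[name] * nrows * ncols))
        _grow_blobs(assigned, target, k, rng)
    landcover: dict[str, FeatureLayer] = {}
    for k, name in enumerate(names, start=1):
        mask = (assigned == k).astype(float)
        landcover[name] = FeatureLayer(
            name,
            RasterGrid(mask, cell_size),
            "facilitator" if name in FACILITATOR_FEATURES else
            ("both" if "wetland" in name or name == "fields" else "barrier"),
        )
    forest_mask = (assigned == 0).astype(float)
    landcover["forest"] = FeatureLayer("forest", RasterGrid(forest_mask, cell_size), "barrier")

    road_layers: dict[int, FeatureLayer] = {}
    for cls in road_classes:
        mask = np.zeros(shape)
        for _ in range(roads_per_class):
            line = _random_crossing_line(template, rng)
            layer = rasterize_polyline(line, template, width_cells=2 if cls == 1 else 1,
                                       name=f"road_class_{cls}", role="barrier")
            mask = np.maximum(mask, layer.mask.values)
        road_layers[cls] = FeatureLayer(
            f"road_class_{cls}", RasterGrid(mask, cell_size), "barrier"
        )
    linear: dict[str, FeatureLayer] = {}
    for name in ("powerline", "railroad"):
        line = _random_crossing_line(template, rng)
        linear[name] = rasterize_polyline(line, template, 1, name=name, role="facilitator")
    lidar = None
    if include_lidar:
        speckle = (rng.random(shape) < LIDAR_COVER).astype(float)
        lidar = FeatureLayer("lidar_veg", RasterGrid(speckle, cell_size), "facilitator")
    return SyntheticLandscape(template, landcover, road_layers, linear, lidar, seed)


def sample_locations(
    landscape: SyntheticLandscape, n: int, seed: int = 0, habitat: str = "scrub_shrub",
) -> list[tuple[int, int]]:
    """Sampling cells drawn from occupied (scrub-shrub) habitat patches."""
    rng = np.random.default_rng(seed)
    mask = landscape.landcover[habitat].cells
    cells = np.argwhere(mask)
    if cells.shape[0] < n:
        cells = np.argwhere(np.ones(landscape.template.shape, dtype=bool))
    pick = rng.choice(cells.shape[0], size=n, replace=False)
    return [tuple(map(int, cells[k])) for k in sorted(pick)]


def gapped_barrier_feature(
    shape: tuple[int, int] = (100, 100),
    n_walls: int = 8,
    gapped_fraction: float = 0.5,
    cell_size: float = 30.0,
    seed: int = 0,
    name: str = "walls",
) -> FeatureLayer:
    """Linear barriers, some pierced by one-cell gaps — a calibration layer.

    Evenly spaced one-cell-wide walls span the grid.  A fraction of them
    carry a single gap at a random position: crossing such a wall costs its
    resistance value while detouring to the gap costs extra background
    distance, so the least-cost route flips from crossing to detouring at a
    resistance comparable to the detour length.  The remaining walls are
    complete, making crossings mandatory so pair costs stay linear in the
    tested value with no upper saturation.  The mixture keeps the
    cost-distance pattern sensitive to the resistance value across the whole
    sanctioned grid, which blob-shaped landcover is not (paths either always
    cross it or always skirt it), making this layer the right substrate for
    testing whether optimization recovers a known generating value.
    """
    rng = np.random.default_rng(seed)
    nrows, ncols = shape
    mask = np.zeros(shape)
    xs = np.linspace(8, ncols - 9, n_walls).astype(int)
    n_gapped = int(round(gapped_fraction * n_walls))
    gapped = set(rng.choice(n_walls, size=n_gapped, replace=False).tolist())
    for k, x in enumerate(xs):
        mask[:, x] = 1.0
        if k in gapped:
            mask[int(rng.integers(0, nrows)), x] = 0.0
    return FeatureLayer(name, RasterGrid(mask, cell_size), "barrier")


def sample_free_cells(layer: FeatureLayer, n: int, seed: int = 0) -> list[tuple[int, int]]:
    """n distinct cells off the feature, uniformly at random."""
    rng = np.random.default_rng(seed)
    cells = np.argwhere(~layer.cells)
    pick = rng.choice(cells.shape[0], size=n, replace=False)
    return [tuple(map(int, cells[k])) for k in sorted(pick)]


# ---------------------------------------------------------------------------
# Pairwise generator (direct isolation-by-resistance data)
# ---------------------------------------------------------------------------


def generate_pairwise_genetic(
    cost: DistanceMatrix,
    beta_true: float = 0.5,
    noise_sd: float = 0.5,
    rho: float = 0.25,
    mu: float = 0.0,
    seed: int = 0,
    kind: str = "genetic_a",
) -> DistanceMatrix:
    """Genetic distances as a linear function of cost distance plus MLPE noise.

    y_ij = mu + beta_true * z(cost_ij) + u_i + u_j + e_ij with
    var(u) = rho * noise_sd^2 and var(e) = (1 - 2 rho) * noise_sd^2, so the
    total noise variance is noise_sd^2 and the correlation between
    observations sharing exactly one individual is rho.
    """
    if beta_true < 0:
        raise SynthError("beta_true must be >= 0")
    if not 0 <= rho <= 0.5:
        raise SynthError("rho must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    n = cost.n
    i, j = np.tril_indices(n, k=-1)
    x = cost.values[i, j]
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    u = rng.normal(0.0, np.sqrt(rho) * noise_sd, size=n)
    e = rng.normal(0.0, np.sqrt(max(0.0, 1.0 - 2.0 * rho)) * noise_sd, size=i.size)
    y = mu + beta_true * z + u[i] + u[j] + e
    out = np.zeros((n, n))
    out[i, j] = y
    out[j, i] = y
    return DistanceMatrix(list(cost.labels), out, kind)


# ---------------------------------------------------------------------------
# Forward-time generator (finite-island stepwise-mutation microsatellites)
# ---------------------------------------------------------------------------


def migration_matrix(cost: DistanceMatrix, lam: float, emigration: float = 0.2) -> np.ndarray:
    """Row-stochastic deme migration with m_ab proportional to exp(-lam*cost).

    Each row's total emigration is ``emigration`` (self-retention >= 0.8),
    split over destinations in proportion to exp(-lam * cost); demes whose
    every destination weight underflows to 0 retain all lineages.
    """
    if emigration > 0.2 + 1e-12:
        raise SynthError("self-retention must be >= 0.8 (emigration <= 0.2)")
    c = cost.values
    with np.errstate(over="ignore", under="ignore"):
        w = np.exp(-lam * np.where(np.isfinite(c), c, np.inf))
    np.fill_diagonal(w, 0.0)
    if np.any(~np.isfinite(w)):
        raise SynthError("unnormalizable migration row (non-finite weights)")
    M = np.zeros_like(w)
    for a in range(w.shape[0]):
        s = w[a].sum()
        if s > 0:
            M[a] = emigration * w[a] / s
        M[a, a] = 1.0 - M[a].sum()
    return M


def simulate_genotypes_forward(
    patch_cells,
    cost: DistanceMatrix,
    lam: float = 1e-3,
    deme_size: int = 50,
    mutation_rate: float = 1e-3,
    n_generations: int = 200,
    n_loci: int = 11,
    sample_sizes=None,
    seed: int = 0,
    template: RasterGrid | None = None,
    emigration: float = 0.2,
) -> GenotypeTable:
    """Forward simulation of microsatellite genotypes over habitat patches.

    Each patch is a deme of ``deme_size`` diploids.  Every generation each
    gene copy picks a parent deme from the migration matrix and a random
    parental gene copy from that deme, then mutates +/-1 repeat unit with
    probability ``mutation_rate`` (stepwise mutation; allele codes are repeat
    counts starting at 50).  Samples of ``sample_sizes[d]`` individuals per
    deme are georeferenced at the patch cell (cell center when a template
    grid is supplied, else cell indices as coordinates).
    """
    rng = np.random.default_rng(seed)
    n_demes = cost.n
    if len(patch_cells) != n_demes:
        raise SynthError("patch_cells and cost matrix disagree on deme count")
    if sample_sizes is None:
        sample_sizes = [min(10, deme_size)] * n_demes
    M = migration_matrix(cost, lam, emigration)
    two_n = 2 * deme_size
    genes = np.full((n_loci, n_demes, two_n), 50, dtype=int)
    for _ in range(n_generations):
        new = np.empty_like(genes)
        for d in range(n_demes):
            src = rng.choice(n_demes, size=two_n, p=M[d])
            pick = rng.integers(0, two_n, size=two_n)
            new[:, d, :] = genes[:, src, pick]
        mut = rng.random(genes.shape) < mutation_rate
        step = rng.integers(0, 2, size=genes.shape) * 2 - 1
        genes = new + np.where(mut, step, 0)
        np.clip(genes, 2, None, out=genes)
    individuals, calls, coords, areas = [], [], [], []
    for d, (r, c) in enumerate(patch_cells):
        take = sample_sizes[d]
        if take > deme_size:
            raise SynthError(f"deme {d}: sample {take} exceeds deme size {deme_size}")
        order = rng.permutation(deme_size)[:take]
        if template is not None:
            x, y = template.cell_center(r, c)
        else:
            x, y = float(c), float(r)
        for k, ind in enumerate(order):
            individuals.append(f"d{d}_i{int(ind)}")
            calls.append(genes[:, d, [2 * ind, 2 * ind + 1]])
            # tiny deterministic jitter keeps locations unique within a patch
            coords.append((x + 0.001 * k, y + 0.001 * k))
            areas.append(str(cost.labels[d]))
    return GenotypeTable(individuals, [f"L{k+1}" for k in range(n_loci)],
                         np.array(calls), np.array(coords), areas)
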