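"""Config-driven orchestration of the two-step landscape-genetics analysis.

Per study area: pairwise distances -> univariate resistance optimization
(partial Mantel stage) -> univariate mixed-model table -> multivariate
surfaces (including buffered roads and the optional short-vegetation layer)
-> multivariate mixed-model table.  Across areas: reconciliation of
per-area optima (per-area / average / maximum feature values scored by
partial Mantel r over the full extent) -> corridor mapping with least-cost
paths and all-to-one circuit analysis.

Everything is seeded; rerunning the same config yields byte-identical
outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circuit as circuit_mod
from .cost import (
    cost_distance_matrix,
    least_cost_path,
    paths_to_count_raster,
    surface_graph,
    write_paths_geojson,
)
from .genetics import DistanceMatrix
from .mantel import partial_mantel
from .mlpe import mlpe_fit, rank_models
from .optimize import optimize_univariate
from .raster import (
    BARRIER_VALUE_GRID,
    DUAL_ROLE_FEATURES,
    MODEL_PRESETS,
    RasterGrid,
    build_univariate_surface,
    compose_multivariate_surface,
)
from .synth import (
    CAPE_LIKE,
    CAPE_ROAD_CLASSES,
    KITTERY_LIKE,
    KITTERY_ROAD_CLASSES,
    generate_landscape,
    generate_pairwise_genetic,
    sample_locations,
)

AREA_DEFAULTS = {
    "kittery_like": {"composition": KITTERY_LIKE, "road_classes": KITTERY_ROAD_CLASSES,
                     "include_lidar": False},
    "cape_like": {"composition": CAPE_LIKE, "road_classes": CAPE_ROAD_CLASSES,
                  "include_lidar": True},
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int
    shape: tuple[int, int] = (80, 80)
    cell_size: float = 30.0
    areas: list[dict] = field(default_factory=lambda: [
        {"name": "kittery_like", "n_individuals": 30},
        {"name": "cape_like", "n_individuals": 40},
    ])
    genetic_metric: str = "genetic_a"
    value_grid: tuple = BARRIER_VALUE_GRID
    optimize_features: list[str] = field(default_factory=lambda: [
        "forest", "development", "scrub_shrub", "fields", "water",
    ])
    presets: list[str] = field(default_factory=lambda: [
        "all_barriers", "natural_barriers", "natural_facilitators",
        "all_facilitators", "linear_facilitators", "landcover",
        "development_roads", "global",
    ])
    buffered_classes_variants: dict = field(default_factory=lambda: {
        "major_only": [1, 2, 3], "all_classes": [1, 2, 3, 4, 5, 6],
    })
    reconciliation_modes: list[str] = field(default_factory=lambda: [
        "per_area", "average", "maximum",
    ])
    n_perm: int = 499
    # truth of the synthetic study: the generating surface
    truth: dict = field(default_factory=lambda: {
        "barriers": {"forest": 100, "development": 250, "roads": 250},
        "facilitators": ["scrub_shrub", "powerline", "railroad"],
        "beta_true": 0.7,
        "noise_sd": 0.4,
        "rho": 0.25,
    })

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise PipelineError("config must set an explicit seed")
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        if "value_grid" in raw:
            raw["value_grid"] = tuple(raw["value_grid"])
        return cls(**raw)


def _resolve_role(name: str, role: str) -> str:
    if role != "both":
        return role
    # dual-role features default to the direction found for them empirically:
    # scrub-shrub and palustrine emergent wetlands facilitate, the rest impede
    return "facilitator" if name in {"scrub_shrub_wetland",
                                     "palustrine_emergent_wetland"} else "barrier"


def _build_area(area_cfg: dict, cfg: RunConfig, seed: int):
    name = area_cfg["name"]
    defaults = AREA_DEFAULTS.get(name, AREA_DEFAULTS["kittery_like"])
    landscape = generate_landscape(
        composition=area_cfg.get("composition", defaults["composition"]),
        shape=cfg.shape,
        cell_size=cfg.cell_size,
        road_classes=area_cfg.get("road_classes", defaults["road_classes"]),
        include_lidar=area_cfg.get("include_lidar", defaults["include_lidar"]),
        seed=seed,
    )
    n = area_cfg.get("n_individuals", 30)
    points = sample_locations(landscape, n, seed=seed + 1)
    labels = [f"{name}_{k}" for k in range(n)]
    return landscape, points, labels


def _true_surface(landscape, truth: dict):
    features = []
    layers = landscape.all_layers()
    for fname, value in truth.get("barriers", {}).items():
        if fname == "roads":
            continue
        if fname in layers:
            features.append((layers[fname], "barrier", float(value)))
    for fname in truth.get("facilitators", []):
        if fname in layers:
            features.append((layers[fname], "facilitator", 1.0))
    road_value = truth.get("barriers", {}).get("roads")
    road_spec = None
    if road_value is not None and landscape.road_layers:
        road_spec = (
            landscape.road_layers,
            {cls: float(road_value) for cls in landscape.road_layers},
            frozenset(),
        )
    return compose_multivariate_surface(features, road_spec)


def _geographic_matrix(landscape, points, labels) -> DistanceMatrix:
    centers = np.array([landscape.template.cell_center(r, c) for r, c in points])
    d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(labels, d, "geographic")


def _multivariate_surface(landscape, preset: str, optimized: dict[str, float],
                          buffered_classes=frozenset()):
    """Assemble a preset's surface from optimized univariate values."""
    spec = MODEL_PRESETS[preset]
    layers = landscape.all_layers()
    features = []
    for fname in spec["barriers"]:
        if fname == "roads":
            continue
        if fname in layers:
            features.append((layers[fname], "barrier",
                             float(optimized.get(fname, 100.0))))
    for fname in spec["facilitators"]:
        if fname in {"roadsides"}:
            continue
        if fname in layers:
            features.append((layers[fname], "facilitator", 1.0))
    road_spec = None
    include_roads = "roads" in spec["barriers"]
    include_roadsides = "roadsides" in spec["facilitators"]
    if landscape.road_layers and (include_roads or include_roadsides):
        values = {cls: float(optimized.get(f"road_class_{cls}",
                                           optimized.get("roads", 250.0)))
                  if include_roads else 1.0
                  for cls in landscape.road_layers}
        buffered = frozenset(buffered_classes) if include_roadsides else frozenset()
        road_spec = (landscape.road_layers, values, buffered)
    if not features and road_spec is None:
        raise PipelineError(f"preset {preset!r} selects no features on this landscape")
    return compose_multivariate_surface(features, road_spec)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full two-step analysis plus corridor mapping.

    Returns the manifest (also written to ``<outdir>/manifest.yaml``) listing
    every seed, selected value, table and raster produced.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_master = np.random.default_rng(cfg.seed)
    manifest: dict = {"seed": cfg.seed, "areas": {}, "files": []}

    area_results = {}
    for a_idx, area_cfg in enumerate(cfg.areas):
        name = area_cfg["name"]
        area_seed = cfg.seed + 1000 * (a_idx + 1)
        landscape, points, labels = _build_area(area_cfg, cfg, area_seed)
        truth_surface = _true_surface(landscape, cfg.truth)
        cost_true = cost_distance_matrix(truth_surface, points, labels=labels).distances
        if not np.all(np.isfinite(cost_true.values)):
            raise PipelineError(f"area {name}: disconnected sampling locations")
        genetic = generate_pairwise_genetic(
            cost_true,
            beta_true=cfg.truth.get("beta_true", 0.7),
            noise_sd=cfg.truth.get("noise_sd", 0.4),
            rho=cfg.truth.get("rho", 0.25),
            seed=area_seed + 7,
            kind=cfg.genetic_metric,
        )
        geographic = _geographic_matrix(landscape, points, labels)
        genetic.write_csv(out / f"{name}_genetic.csv")
        geographic.write_csv(out / f"{name}_geographic.csv")

        # -- univariate optimization (Mantel stage) -------------------------
        traces = []
        optimized: dict[str, float] = {}
        layers = landscape.all_layers()
        for fname in cfg.optimize_features:
            if fname not in layers:
                continue
            layer = layers[fname]
            modes = (
                ["barrier", "facilitator"] if layer.role == "both"
                else [layer.role]
            )
            best = None
            for mode in modes:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tr = optimize_univariate(
                        layer, mode, genetic, geographic, points,
                        value_grid=cfg.value_grid, n_perm=cfg.n_perm,
                        seed=area_seed + 13,
                    )
                traces.append(tr)
                score = max(tr.partial_r) if tr.partial_r else -np.inf
                if best is None or score > best[0]:
                    best = (score, mode, tr.selected_value)
            optimized[fname] = best[2] if best[1] == "barrier" else 1.0
        # roads optimized as one combined barrier feature
        roads = landscape.roads_combined()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr_roads = optimize_univariate(
                roads, "barrier", genetic, geographic, points,
                value_grid=cfg.value_grid, n_perm=cfg.n_perm, seed=area_seed + 13,
            )
        traces.append(tr_roads)
        optimized["roads"] = tr_roads.selected_value
        trace_df = pd.concat([t.to_frame() for t in traces], ignore_index=True)
        trace_df.to_csv(out / f"{name}_optimization_trace.csv", index=False)

        # -- univariate mixed-model table (per-feature ranking) -------------
        uni_fits = {}
        for fname, value in optimized.items():
            if fname == "roads":
                surface = compose_multivariate_surface(
                    [], (landscape.road_layers,
                         {cls: value for cls in landscape.road_layers}, frozenset()))
            else:
                layer = layers[fname]
                mode = "facilitator" if value == 1.0 and layer.role != "barrier" else "barrier"
                surface = build_univariate_surface(layer, mode,
                                                   value if mode == "barrier" else 1.0,
                                                   value_grid=cfg.value_grid)
            eff = cost_distance_matrix(surface, points, labels=labels).distances
            if np.all(np.isfinite(eff.values)):
                uni_fits[fname] = mlpe_fit(genetic, eff)
        uni_fits["null"] = mlpe_fit(genetic, geographic)
        uni_table = rank_models(uni_fits)
        uni_table.to_csv(out / f"{name}_univariate_models.csv", index=False)

        # -- multivariate surfaces and table --------------------------------
        multi_fits = {}
        for preset in cfg.presets:
            try:
                surface = _multivariate_surface(landscape, preset, optimized)
            except PipelineError:
                continue
            eff = cost_distance_matrix(surface, points, labels=labels).distances
            if np.all(np.isfinite(eff.values)):
                multi_fits[preset] = mlpe_fit(genetic, eff)
        for variant, classes in cfg.buffered_classes_variants.items():
            surface = _multivariate_surface(
                landscape, "global", optimized,
                buffered_classes=frozenset(classes) & set(landscape.road_layers),
            )
            eff = cost_distance_matrix(surface, points, labels=labels).distances
            if np.all(np.isfinite(eff.values)):
                multi_fits[f"global_buffered_{variant}"] = mlpe_fit(genetic, eff)
        multi_fits["null"] = mlpe_fit(genetic, geographic)
        multi_table = rank_models(multi_fits)
        multi_table.to_csv(out / f"{name}_multivariate_models.csv", index=False)

        area_results[name] = {
            "landscape": landscape, "points": points, "labels": labels,
            "optimized": optimized, "genetic": genetic, "geographic": geographic,
            "uni_table": uni_table, "multi_table": multi_table,
        }
        manifest["areas"][name] = {
            "seed": area_seed,
            "optimized_values": {k: float(v) for k, v in optimized.items()},
            "best_univariate": str(uni_table["Model"].iloc[0]),
            "best_multivariate": str(multi_table["Model"].iloc[0]),
        }
        manifest["files"] += [
            f"{name}_genetic.csv", f"{name}_geographic.csv",
            f"{name}_optimization_trace.csv", f"{name}_univariate_models.csv",
            f"{name}_multivariate_models.csv",
        ]

    # -- reconciliation across areas on the full extent ---------------------
    full_seed = cfg.seed + 77
    full_cfg = {"name": "kittery_like", "n_individuals":
                sum(a.get("n_individuals", 30) for a in cfg.areas)}
    full_landscape, full_points, full_labels = _build_area(full_cfg, cfg, full_seed)
    truth_surface = _true_surface(full_landscape, cfg.truth)
    cost_true = cost_distance_matrix(truth_surface, full_points, labels=full_labels).distances
    full_genetic = generate_pairwise_genetic(
        cost_true, beta_true=cfg.truth.get("beta_true", 0.7),
        noise_sd=cfg.truth.get("noise_sd", 0.4), rho=cfg.truth.get("rho", 0.25),
        seed=full_seed + 7, kind=cfg.genetic_metric,
    )
    full_geo = _geographic_matrix(full_landscape, full_points, full_labels)

    area_names = list(area_results)
    opt_sets = [area_results[a]["optimized"] for a in area_names]
    all_features = sorted(set().union(*[set(o) for o in opt_sets]))

    def reconciled(mode: str, which: int = 0) -> dict[str, float]:
        vals = {}
        for f in all_features:
            present = [o[f] for o in opt_sets if f in o]
            if mode == "per_area":
                vals[f] = opt_sets[which].get(f, present[0])
            elif mode == "average":
                vals[f] = float(np.mean(present))
            else:
                vals[f] = float(np.max(present))
        return vals

    candidates: dict[str, dict[str, float]] = {}
    for mode in cfg.reconciliation_modes:
        if mode == "per_area":
            for w, a in enumerate(area_names):
                candidates[f"per_area_{a}"] = reconciled("per_area", w)
        else:
            candidates[mode] = reconciled(mode)
    recon_rows = []
    best = None
    for label, values in candidates.items():
        surface = _multivariate_surface(full_landscape, "global", values,
                                        buffered_classes=frozenset({1, 2, 3}))
        eff = cost_distance_matrix(surface, full_points, labels=full_labels).distances
        if not np.all(np.isfinite(eff.values)):
            recon_rows.append((label, np.nan, np.nan))
            continue
        res = partial_mantel(full_genetic, eff, full_geo, n_perm=cfg.n_perm,
                             seed=full_seed + 13)
        recon_rows.append((label, res.r, res.p))
        if best is None or res.r > best[1]:
            best = (label, res.r, values, surface)
    if best is None:
        raise PipelineError("reconciliation: every candidate surface was disconnected")
    recon_df = pd.DataFrame(recon_rows, columns=["reconciliation", "partial_r", "p"])
    recon_df.to_csv(out / "reconciliation.csv", index=False)
    manifest["reconciliation"] = {"best": best[0], "partial_r": float(best[1])}
    manifest["files"] += ["reconciliation.csv"]

    # -- corridors on the best full-extent surface ---------------------------
    best_surface = best[3]
    best_surface.grid.write_ascii(out / "best_surface.asc")
    corridor = map_corridors(best_surface, full_points, out_prefix=out / "corridor")
    manifest["corridor"] = corridor["summary"]
    manifest["files"] += ["best_surface.asc"] + corridor["files"]

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def map_corridors(surface, points, focal_masks=None, out_prefix=None) -> dict:
    """LCP corridor network plus all-to-one current maps, with divergence layer.

    The least-cost-path network over all point pairs is rasterized to a
    path-count grid; circuit analysis runs in all-to-one mode over the
    individual sampling cells and, when ``focal_masks`` is given, over focal
    patches contracted to super-nodes.  The divergence layer marks cells in
    the top decile of current flow that carry no least-cost path — the areas
    where the two corridor views disagree.
    """
    graph, _ = surface_graph(surface)
    paths = {}
    for a in range(len(points)):
        for b in range(a + 1, len(points)):
            cells, _ = least_cost_path(surface, points[a], points[b], _graph=graph)
            paths[(a, b)] = cells
    count = paths_to_count_raster(surface, paths)

    net = circuit_mod.build_network(surface)
    focal_nodes = [circuit_mod.node_of_point(net, r, c) for r, c in points]
    current_ind = circuit_mod.solve_all_to_one(net, focal_nodes, template=surface.grid)
    cur = current_ind.grid.values
    results: dict = {"path_count": count, "current_individual": cur}
    if focal_masks is not None:
        cnet, focals = circuit_mod.contract_focal_patches(net, focal_masks)
        current_patch = circuit_mod.solve_all_to_one(cnet, focals, template=surface.grid)
        results["current_patches"] = current_patch.grid.values

    pos = cur[cur > 0]
    top = np.quantile(pos, 0.9) if pos.size else np.inf
    divergence = (cur >= top) & (count == 0)
    results["divergence"] = divergence
    results["summary"] = {
        "n_lcp_cells": int((count > 0).sum()),
        "n_top_current_cells": int((cur >= top).sum()),
        "n_divergent_cells": int(divergence.sum()),
    }
    files = []
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        g = surface.grid
        for key in ("path_count", "current_individual", "current_patches", "divergence"):
            if key not in results:
                continue
            RasterGrid(np.asarray(results[key], dtype=float), g.cell_size,
                       g.origin_x, g.origin_y, g.nodata.copy()).write_ascii(
                f"{out_prefix}_{key}.asc")
            files.append(f"{out_prefix.name}_{key}.asc")
        write_paths_geojson(surface, paths, f"{out_prefix}_lcp.geojson")
        files.append(f"{out_prefix.name}_lcp.geojson")
        with open(f"{out_prefix}_summary.json", "w") as fh:
            json.dump(results["summary"], fh, indent=2, sort_keys=True)
        files.append(f"{out_prefix.name}_summary.json")
    results["files"] = files
    return results
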