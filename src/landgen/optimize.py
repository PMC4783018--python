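"""Constrained univariate optimization of per-feature resistance values.

For each landscape feature a grid of candidate resistance values is tested:
the feature is written into a binary friction surface, cost distances are
computed between all sampling locations, and the partial Mantel correlation
of effective with genetic distance (controlling for geographic distance)
scores the candidate.  The selected value is the unimodal peak of the
correlation profile, or where the profile plateaus, the onset of the plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cost import cost_distance_matrix
from .genetics import DistanceMatrix
from .mantel import partial_mantel
from .raster import BARRIER_VALUE_GRID, FeatureLayer, build_univariate_surface


class OptimizeError(ValueError):
    pass


@dataclass
class OptimizationTrace:
    feature: str
    mode: str  # "barrier" | "facilitator"
    tested_values: list[float]
    partial_r: list[float]
    p: list[float]
    selected_value: float | None = None
    rule_applied: str | None = None
    skipped_values: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature,
                "mode": self.mode,
                "value": self.tested_values,
                "partial_r": self.partial_r,
                "p": self.p,
                "selected": [v == self.selected_value for v in self.tested_values],
            }
        )


def select_resistance(trace: OptimizationTrace, rel_tol: float = 0.01) -> float:
    """Peak/plateau selection rule on the partial Mantel r profile.

    If the global maximum is a strict interior peak (greater than both grid
    neighbors), that value is selected.  Otherwise the profile is treated as
    plateauing and the smallest value whose r reaches (1 - rel_tol) x max r
    is selected.  If no candidate has positive support the smallest value is
    returned with a warning.
    """
    if not trace.tested_values:
        raise OptimizeError("empty trace")
    r = np.asarray(trace.partial_r, dtype=float)
    vals = np.asarray(trace.tested_values, dtype=float)
    order = np.argsort(vals)
    vals, r = vals[order], r[order]
    if np.all(r <= 0):
        warnings.warn("no support: all partial Mantel r non-positive", stacklevel=2)
        trace.selected_value = float(vals[0])
        trace.rule_applied = "no_support"
        return trace.selected_value
    k = int(np.argmax(r))
    if 0 < k < len(r) - 1 and r[k] > r[k - 1] and r[k] > r[k + 1]:
        trace.selected_value = float(vals[k])
        trace.rule_applied = "peak"
        return trace.selected_value
    rmax = r.max()
    cutoff = (1.0 - rel_tol) * rmax if rmax > 0 else rmax
    onset = int(np.argmax(r >= cutoff))
    trace.selected_value = float(vals[onset])
    trace.rule_applied = "plateau"
    return trace.selected_value


def optimize_univariate(
    feature: FeatureLayer,
    mode: str,
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    points,
    value_grid=BARRIER_VALUE_GRID,
    n_perm: int = 999,
    seed: int = 0,
    rel_tol: float = 0.01,
    cost_cache: dict | None = None,
) -> OptimizationTrace:
    """Grid-search the resistance value for one feature in one mode.

    ``points`` are snapped (row, col) sampling cells ordered like the
    distance-matrix labels.  Facilitator mode evaluates the single 1-vs-100
    surface.  Candidates leaving any sampling pair disconnected are skipped
    with a warning.  ``cost_cache`` (keyed by (feature, mode, value)) lets
    callers reuse cost matrices across datasets on the same landscape.
    """
    if genetic.labels != geographic.labels:
        raise OptimizeError("genetic and geographic matrices have mismatched labels")
    candidates = [1.0] if mode == "facilitator" else [float(v) for v in value_grid]
    trace = OptimizationTrace(feature.name, mode, [], [], [])
    for value in candidates:
        key = (feature.name, mode, value)
        if cost_cache is not None and key in cost_cache:
            eff = cost_cache[key]
        else:
            surface = build_univariate_surface(feature, mode, value, value_grid=value_grid)
            eff = cost_distance_matrix(surface, points, labels=genetic.labels).distances
            if cost_cache is not None:
                cost_cache[key] = eff
        if not np.all(np.isfinite(eff.values)):
            warnings.warn(
                f"{feature.name} ({mode}) value {value}: disconnected pairs, skipped",
                stacklevel=2,
            )
            trace.skipped_values.append(value)
            continue
        res = partial_mantel(genetic, eff, geographic, n_perm=n_perm, seed=seed)
        trace.tested_values.append(value)
        trace.partial_r.append(res.r)
        trace.p.append(res.p)
    if not trace.tested_values:
        raise OptimizeError(f"{feature.name}: every candidate left pairs disconnected")
    select_resistance(trace, rel_tol=rel_tol)
    return trace
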