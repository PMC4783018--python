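"""Raster model, polyline tracing, and resistance-surface construction."""

import numpy as np
import pytest

from landgen.raster import (
    BARRIER_VALUE_GRID,
    FeatureLayer,
    RasterError,
    RasterGrid,
    build_buffered_road_surface,
    build_univariate_surface,
    compose_multivariate_surface,
    rasterize_polyline,
)

from conftest import feature_from_mask


def segment_hits_cell(x0, y0, x1, y1, cx0, cy0, cx1, cy1) -> bool:
    """Brute-force segment / closed-box intersection (Liang-Barsky clip)."""
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - cx0),
        (dx, cx1 - x0),
        (-dy, y0 - cy0),
        (dy, cy1 - y0),
    ):
        if p == 0:
            if q < 0:
                return False
        else:
            t = q / p
            if p < 0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
    return t0 <= t1


def supercover_oracle(verts, grid: RasterGrid) -> np.ndarray:
    """Mark every cell whose square any segment intersects (exact clip test)."""
    mask = np.zeros(grid.shape, dtype=bool)
    top = grid.origin_y + grid.nrows * grid.cell_size
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        for r in range(grid.nrows):
            for c in range(grid.ncols):
                cx0 = grid.origin_x + c * grid.cell_size
                cx1 = cx0 + grid.cell_size
                cy1 = top - r * grid.cell_size
                cy0 = cy1 - grid.cell_size
                if segment_hits_cell(x0, y0, x1, y1, cx0, cy0, cx1, cy1):
                    mask[r, c] = True
    return mask


class TestRasterGrid:
    def test_invalid_inputs_rejected(self):
        with pytest.raises(RasterError):
            RasterGrid(np.ones((3, 3)), 0.0)
        with pytest.raises(RasterError):
            RasterGrid(np.array([[1.0, np.nan], [1.0, 1.0]]), 30.0)

    def test_snap_and_cell_center_round_trip(self, grid5):
        for r in range(5):
            for c in range(5):
                x, y = grid5.cell_center(r, c)
                assert grid5.snap(x, y) == (r, c)

    def test_ascii_round_trip(self, tmp_path, grid5):
        vals = np.arange(25, dtype=float).reshape(5, 5) + 1
        nodata = np.zeros((5, 5), bool)
        nodata[0, 0] = True
        g = RasterGrid(vals, 30.0, 100.0, 200.0, nodata)
        path = tmp_path / "g.asc"
        g.write_ascii(path)
        back = RasterGrid.read_ascii(path)
        assert back.cell_size == 30.0
        assert back.origin_x == 100.0
        assert np.array_equal(back.nodata, nodata)
        assert np.allclose(back.values[~nodata], vals[~nodata])


class TestRasterizePolyline:
    def test_horizontal_line_width_one(self, grid5):
        layer = rasterize_polyline([(0.1, 75.0), (149.9, 75.0)], grid5, 1)
        assert layer.mask.values.sum() == 5
        assert layer.mask.values[2].sum() == 5  # row 2: y=75 is the middle row

    def test_horizontal_line_width_two(self, grid5):
        layer = rasterize_polyline([(0.1, 75.0), (149.9, 75.0)], grid5, 2)
        assert layer.mask.values.sum() == 10
        rows = np.flatnonzero(layer.mask.values.any(axis=1))
        assert len(rows) == 2 and rows[1] == rows[0] + 1

    def test_diagonal_matches_brute_force_oracle(self):
        g = RasterGrid(np.ones((4, 4)), 30.0)
        verts = [(0.1, 0.1), (119.9, 119.9)]
        layer = rasterize_polyline(verts, g, 1)
        oracle = supercover_oracle(verts, g)
        assert np.array_equal(layer.mask.values.astype(bool), oracle)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_segments_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = RasterGrid(np.ones((6, 6)), 30.0)
        verts = [tuple(rng.uniform(1, 179, 2)) for _ in range(3)]
        layer = rasterize_polyline(verts, g, 1)
        oracle = supercover_oracle(verts, g)
        assert np.array_equal(layer.mask.values.astype(bool), oracle)

    def test_traced_path_is_8_connected(self):
        rng = np.random.default_rng(7)
        g = RasterGrid(np.ones((20, 20)), 30.0)
        verts = [tuple(rng.uniform(1, 599, 2)) for _ in range(2)]
        mask = rasterize_polyline(verts, g, 1).mask.values.astype(bool)
        from scipy.ndimage import label

        _, n_comp = label(mask, structure=np.ones((3, 3)))
        assert n_comp == 1

    def test_errors(self, grid5):
        with pytest.raises(RasterError):
            rasterize_polyline([], grid5, 1)
        with pytest.raises(RasterError, match="outside"):
            rasterize_polyline([(0.0, 0.0), (1000.0, 0.0)], grid5, 1)
        with pytest.raises(RasterError):
            rasterize_polyline([(10.0, 10.0), (20.0, 20.0)], grid5, 3)


class TestUnivariateSurface:
    def test_barrier_assigns_value_on_feature(self):
        mask = np.zeros((4, 4))
        mask[1, 1] = mask[2, 2] = 1
        feat = feature_from_mask(mask, "forest")
        s = build_univariate_surface(feat, "barrier", 10)
        assert s.grid.values[1, 1] == 10 and s.grid.values[2, 2] == 10
        assert s.grid.values[0, 0] == 1

    def test_facilitator_background_100(self):
        mask = np.zeros((4, 4))
        mask[0, 0] = 1
        feat = feature_from_mask(mask, "scrub_shrub", role="facilitator")
        s = build_univariate_surface(feat, "facilitator")
        assert s.grid.values[0, 0] == 1
        assert s.grid.values[3, 3] == 100

    def test_empty_mask_barrier_is_uniform_one(self):
        feat = feature_from_mask(np.zeros((4, 4)))
        s = build_univariate_surface(feat, "barrier", 50)
        assert np.all(s.grid.values == 1)

    def test_unsanctioned_value_rejected(self):
        feat = feature_from_mask(np.ones((3, 3)))
        with pytest.raises(RasterError, match="sanctioned"):
            build_univariate_surface(feat, "barrier", 37)
        # configurable grid admits it
        s = build_univariate_surface(feat, "barrier", 37, value_grid=(37,))
        assert np.all(s.grid.values == 37)


class TestBufferedRoads:
    def road_row(self, row=3, shape=(7, 7), cls=1):
        mask = np.zeros(shape)
        mask[row, :] = 1
        return {cls: feature_from_mask(mask, f"road_class_{cls}")}

    def test_single_road_row_flanked_by_buffer(self):
        layers = self.road_row()
        s = build_buffered_road_surface(layers, {1: 250.0}, {1})
        assert np.all(s.grid.values[3] == 250)
        assert np.all(s.grid.values[2] == 1) and np.all(s.grid.values[4] == 1)
        assert np.all(s.grid.values[0] == 1)  # untouched background is 1 anyway

    def test_no_buffer_reduces_to_barrier_only(self):
        layers = self.road_row()
        s = build_buffered_road_surface(layers, {1: 250.0}, set())
        expected = build_univariate_surface(layers[1], "barrier", 250).grid.values
        assert np.array_equal(s.grid.values, expected)

    def test_two_parallel_roads_hand_enumeration(self):
        # roads on rows 2 and 4 (one free row between), 7x7, both buffered
        m1 = np.zeros((7, 7)); m1[2, :] = 1
        m2 = np.zeros((7, 7)); m2[4, :] = 1
        layers = {2: feature_from_mask(m1, "road_class_2"),
                  3: feature_from_mask(m2, "road_class_3")}
        s = build_buffered_road_surface(layers, {2: 100.0, 3: 50.0}, {2, 3})
        expected = np.ones((7, 7))
        expected[2, :] = 100.0
        expected[4, :] = 50.0
        expected[1, :] = expected[3, :] = expected[5, :] = 1.0
        assert np.array_equal(s.grid.values, expected)

    def test_overlap_highest_resistance_wins(self):
        m = np.zeros((5, 5)); m[2, :] = 1
        layers = {1: feature_from_mask(m, "road_class_1"),
                  4: feature_from_mask(m, "road_class_4")}
        s = build_buffered_road_surface(layers, {1: 750.0, 4: 25.0}, set())
        assert np.all(s.grid.values[2] == 750)

    def test_buffer_never_overwrites_road_cells(self):
        # adjacent roads: buffer of one class must not erase the other's cells
        m1 = np.zeros((5, 5)); m1[2, :] = 1
        m2 = np.zeros((5, 5)); m2[3, :] = 1
        layers = {1: feature_from_mask(m1, "road_class_1"),
                  5: feature_from_mask(m2, "road_class_5")}
        s = build_buffered_road_surface(layers, {1: 500.0, 5: 10.0}, {1, 5})
        assert np.all(s.grid.values[2] == 500)
        assert np.all(s.grid.values[3] == 10)
        assert np.all(s.grid.values[1] == 1) and np.all(s.grid.values[4] == 1)


def precedence_oracle(shape, features, road_layers, barrier_values, buffered):
    """Cell-by-cell re-evaluation of the documented precedence function."""
    out = np.ones(shape)
    road_cells = np.zeros(shape, bool)
    for cls, layer in road_layers.items():
        road_cells |= layer.cells
    for r in range(shape[0]):
        for c in range(shape[1]):
            v = 1.0
            for cls, layer in road_layers.items():
                if layer.cells[r, c]:
                    v = max(v, barrier_values[cls])
            for layer, role, value in features:
                if role == "barrier" and layer.cells[r, c]:
                    v = max(v, value)
            for layer, role, value in features:
                if role == "facilitator" and layer.cells[r, c] and not road_cells[r, c]:
                    v = 1.0
            if not road_cells[r, c]:
                for cls in buffered:
                    if cls not in road_layers:
                        continue
                    cells = road_layers[cls].cells
                    nb = cells[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
                    if nb.any():
                        v = 1.0
            out[r, c] = v
    return out


class TestComposeMultivariate:
    def test_disjoint_barrier_and_facilitator(self):
        b = np.zeros((5, 5)); b[0, :] = 1
        f = np.zeros((5, 5)); f[4, :] = 1
        s = compose_multivariate_surface(
            [(feature_from_mask(b, "forest"), "barrier", 10.0),
             (feature_from_mask(f, "scrub_shrub"), "facilitator", 1.0)]
        )
        assert np.all(s.grid.values[0] == 10)
        assert np.all(s.grid.values[4] == 1)
        assert np.all(s.grid.values[2] == 1)

    def test_facilitator_overrides_barrier_off_roads(self):
        b = np.zeros((3, 3)); b[1, 1] = 1
        f = np.zeros((3, 3)); f[1, 1] = 1
        s = compose_multivariate_surface(
            [(feature_from_mask(b, "development"), "barrier", 500.0),
             (feature_from_mask(f, "scrub_shrub"), "facilitator", 1.0)]
        )
        assert s.grid.values[1, 1] == 1

    def test_facilitator_does_not_override_road_carriageway(self):
        road = np.zeros((5, 5)); road[2, :] = 1
        f = np.zeros((5, 5)); f[2, 2] = 1
        s = compose_multivariate_surface(
            [(feature_from_mask(f, "powerline", role="facilitator"), "facilitator", 1.0)],
            road_spec=({3: feature_from_mask(road, "road_class_3")}, {3: 100.0}, frozenset()),
        )
        assert s.grid.values[2, 2] == 100

    def test_unresolved_both_role_rejected(self):
        f = feature_from_mask(np.ones((3, 3)), "fields", role="both")
        with pytest.raises(RasterError, match="unresolved"):
            compose_multivariate_surface([(f, "both", 10.0)])

    def test_idempotent_composition(self):
        rng = np.random.default_rng(0)
        feats = [(feature_from_mask(rng.random((8, 8)) < 0.3, "forest"), "barrier", 100.0),
                 (feature_from_mask(rng.random((8, 8)) < 0.2, "scrub_shrub"),
                  "facilitator", 1.0)]
        s1 = compose_multivariate_surface(feats)
        s2 = compose_multivariate_surface(feats)
        assert np.array_equal(s1.grid.values, s2.grid.values)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_cell_precedence_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (20, 20)
        feats = [
            (feature_from_mask(rng.random(shape) < 0.3, "forest"), "barrier", 100.0),
            (feature_from_mask(rng.random(shape) < 0.2, "development"), "barrier", 250.0),
            (feature_from_mask(rng.random(shape) < 0.15, "scrub_shrub"), "facilitator", 1.0),
        ]
        road_mask = np.zeros(shape); road_mask[int(rng.integers(2, 18)), :] = 1
        roads = {2: feature_from_mask(road_mask, "road_class_2")}
        vals = {2: 500.0}
        s = compose_multivariate_surface(feats, road_spec=(roads, vals, frozenset({2})))
        oracle = precedence_oracle(shape, feats, roads, vals, {2})
        assert np.array_equal(s.grid.values, oracle)

    def test_buffered_differs_from_unbuffered_exactly_on_buffer_cells(self):
        # embed the road in a uniform forest barrier so buffer cells are visible
        shape = (9, 9)
        road_mask = np.zeros(shape); road_mask[4, :] = 1
        roads = {1: feature_from_mask(road_mask, "road_class_1")}
        forest = [(feature_from_mask(np.ones(shape), "forest"), "barrier", 10.0)]
        s_buf = compose_multivariate_surface(forest, (roads, {1: 250.0}, frozenset({1})))
        s_bar = compose_multivariate_surface(forest, (roads, {1: 250.0}, frozenset()))
        diff = s_buf.grid.values != s_bar.grid.values
        buffer_cells = np.zeros(shape, bool)
        buffer_cells[3, :] = buffer_cells[5, :] = True
        assert np.array_equal(diff, buffer_cells)
        assert np.all(s_buf.grid.values[3] == 1) and np.all(s_buf.grid.values[5] == 1)
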