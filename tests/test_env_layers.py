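import numpy as np
import pytest

from maxampo.env_layers import (
    PFT_NAMES,
    bilinear_resample,
    filter_records,
    landcover_to_pft,
    mantel_correlogram,
    terrain_derivatives,
    vif_correlation_select,
)
from maxampo.grid import EnvStack, Grid, OccurrenceSet


def metric_grid(n, cell=1.0, origin=None):
    return Grid(n_rows=n, n_cols=n, cell_size=cell, origin=origin or (0.0, n * cell))


class TestBilinearResample:
    def test_constant_source_stays_constant(self):
        src = metric_grid(8)
        tgt = Grid(n_rows=16, n_cols=16, cell_size=0.5, origin=(0.0, 8.0))
        out = bilinear_resample(np.full(src.shape, 3.7), src, tgt)
        np.testing.assert_allclose(out, 3.7)

    def test_exact_on_affine_surface(self):
        src = metric_grid(10)
        xs, ys = src.cell_centres()
        plane = 2.0 + 0.3 * xs[None, :] - 0.7 * ys[:, None]
        tgt = Grid(n_rows=20, n_cols=20, cell_size=0.25, origin=(2.0, 8.0))
        out = bilinear_resample(plane, src, tgt)
        xt, yt = tgt.cell_centres()
        expected = 2.0 + 0.3 * xt[None, :] - 0.7 * yt[:, None]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_midpoint_of_2x2(self):
        # hand evaluation: mean of the 4 neighbours at the centre point
        src = Grid(n_rows=2, n_cols=2, cell_size=1.0, origin=(0.0, 2.0))
        tgt = Grid(n_rows=1, n_cols=1, cell_size=1.0, origin=(0.5, 1.5))
        out = bilinear_resample(np.array([[0.0, 1.0], [2.0, 3.0]]), src, tgt)
        assert out[0, 0] == pytest.approx(1.5)

    def test_nodata_propagates(self):
        src = metric_grid(4)
        layer = np.ones(src.shape)
        layer[1, 1] = np.nan
        tgt = Grid(n_rows=8, n_cols=8, cell_size=0.5, origin=(0.0, 4.0))
        out = bilinear_resample(layer, src, tgt)
        # any target cell using the nan neighbour is nan; far cells are fine
        assert np.isnan(out[2, 2])
        assert out[7, 7] == 1.0

    def test_disjoint_extents_rejected(self):
        src = metric_grid(4)
        tgt = Grid(n_rows=4, n_cols=4, cell_size=1.0, origin=(100.0, 104.0))
        with pytest.raises(ValueError, match="disjoint"):
            bilinear_resample(np.ones(src.shape), src, tgt)

    def test_output_within_input_range(self, rng):
        src = metric_grid(12)
        layer = rng.normal(size=src.shape)
        tgt = Grid(n_rows=30, n_cols=30, cell_size=0.4, origin=(0.0, 12.0))
        out = bilinear_resample(layer, src, tgt)
        assert np.nanmin(out) >= layer.min() - 1e-12
        assert np.nanmax(out) <= layer.max() + 1e-12


class TestTerrainDerivatives:
    def test_flat_dem(self):
        g = metric_grid(8)
        stack = terrain_derivatives(np.full(g.shape, 100.0), g)
        interior = stack["slope"][1:-1, 1:-1]
        np.testing.assert_allclose(interior, 0.0)
        np.testing.assert_allclose(stack["roughness"][1:-1, 1:-1], 0.0)
        # flat aspect is undefined, not "north"
        assert np.all(np.isnan(stack["aspect"][1:-1, 1:-1]))
        # borders are nodata
        assert np.all(np.isnan(stack["slope"][0, :]))

    def test_unit_gradient_plane(self):
        # z = x: 45 degree slope, downslope faces west (270)
        g = metric_grid(8)
        xs, ys = g.cell_centres()
        dem = np.broadcast_to(xs[None, :], g.shape).copy()
        stack = terrain_derivatives(dem, g)
        np.testing.assert_allclose(stack["slope"][1:-1, 1:-1], 45.0)
        np.testing.assert_allclose(stack["aspect"][1:-1, 1:-1], 270.0)
        # z = y: downslope faces south (180)
        dem_y = np.broadcast_to(ys[:, None], g.shape).copy()
        stack_y = terrain_derivatives(dem_y, g)
        np.testing.assert_allclose(stack_y["aspect"][1:-1, 1:-1], 180.0)

    def test_roughness_of_ordered_window(self):
        g = metric_grid(3)
        dem = np.arange(1.0, 10.0).reshape(3, 3)
        stack = terrain_derivatives(dem, g)
        assert stack["roughness"][1, 1] == 8.0

    def test_matches_brute_force_windows(self, rng):
        g = metric_grid(12, cell=25.0)
        dem = rng.normal(scale=50.0, size=g.shape) + 500.0
        stack = terrain_derivatives(dem, g)
        s = g.cell_size
        for i in range(1, 11):
            for j in range(1, 11):
                w = dem[i - 1 : i + 2, j - 1 : j + 2]
                dzdx = (
                    (w[0, 2] + 2 * w[1, 2] + w[2, 2])
                    - (w[0, 0] + 2 * w[1, 0] + w[2, 0])
                ) / (8 * s)
                dzdy = (
                    (w[0, 0] + 2 * w[0, 1] + w[0, 2])
                    - (w[2, 0] + 2 * w[2, 1] + w[2, 2])
                ) / (8 * s)
                slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
                aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360
                assert stack["slope"][i, j] == pytest.approx(slope)
                assert stack["aspect"][i, j] == pytest.approx(aspect)
                assert stack["roughness"][i, j] == w.max() - w.min()

    def test_nodata_window_and_geographic_rejection(self):
        g = metric_grid(5)
        dem = np.ones(g.shape)
        dem[2, 2] = np.nan
        stack = terrain_derivatives(dem, g)
        assert np.isnan(stack["slope"][1, 1])  # window touches the nodata cell
        geo = Grid(n_rows=16, n_cols=16, cell_size=0.001, crs_id="EPSG:4326")
        with pytest.raises(ValueError, match="project"):
            terrain_derivatives(np.ones(geo.shape), geo)


class TestLandcoverToPft:
    CROSSWALK = {
        1: {"tree": 1.0, "shrub": 0.0, "crop": 0.0, "grass": 0.0, "urban": 0.0, "bare": 0.0},
        2: {"tree": 0.5, "shrub": 0.3, "crop": 0.0, "grass": 0.2, "urban": 0.0, "bare": 0.0},
    }

    def test_pure_and_mosaic_rows(self):
        g = metric_grid(4)
        lc = np.ones(g.shape)
        lc[2:, :] = 2
        stack = landcover_to_pft(lc, g, self.CROSSWALK)
        assert stack["tree"][0, 0] == 1.0
        assert stack["tree"][3, 0] == 0.5
        assert stack["shrub"][3, 0] == 0.3
        assert stack["grass"][3, 0] == 0.2
        assert set(stack.names) == set(PFT_NAMES)

    def test_unknown_code_rejected(self):
        g = metric_grid(4)
        lc = np.full(g.shape, 9.0)
        with pytest.raises(ValueError, match="9"):
            landcover_to_pft(lc, g, self.CROSSWALK)

    def test_fractions_survive_downscaling(self, rng):
        # 300 m fractions resampled to 100 m stay in [0,1] and sum <= 1
        coarse = metric_grid(10, cell=300.0)
        lc = rng.choice([1, 2], size=coarse.shape).astype(float)
        stack = landcover_to_pft(lc, coarse, self.CROSSWALK)
        fine = Grid(n_rows=30, n_cols=30, cell_size=100.0, origin=(0.0, 3000.0))
        resampled = {
            n: bilinear_resample(stack[n], coarse, fine) for n in stack.names
        }
        total = sum(resampled.values())
        idx = rng.integers(0, 30, size=(1000, 2))
        for i, j in idx:
            for n in resampled:
                assert -1e-12 <= resampled[n][i, j] <= 1 + 1e-12
            assert total[i, j] <= 1 + 1e-9


class TestVifSelection:
    def _stack_from(self, layers):
        n = next(iter(layers.values())).shape[0]
        g = metric_grid(n)
        return EnvStack(g, layers), g

    def _points(self, g, rng, n=300):
        x = rng.uniform(0, g.x_max, n)
        y = rng.uniform(0, g.y_max, n)
        return (x, y)

    def test_orthogonal_layers_all_kept(self, rng):
        g = metric_grid(30)
        layers = {f"v{i}": rng.normal(size=g.shape) for i in range(3)}
        stack = EnvStack(g, layers)
        rep = vif_correlation_select(stack, self._points(g, rng))
        assert sorted(rep.kept) == ["v0", "v1", "v2"]
        assert all(v < 1.5 for v in rep.vif.values())

    def test_duplicate_layer_dropped_at_correlation_stage(self, rng):
        g = metric_grid(30)
        a = rng.normal(size=g.shape)
        stack = EnvStack(g, {"a": a, "a_copy": a.copy(), "b": rng.normal(size=g.shape)})
        rep = vif_correlation_select(stack, self._points(g, rng))
        assert len(rep.kept) == 2
        assert "b" in rep.kept
        dropped_names = [n for n, _ in rep.dropped]
        assert ("a" in dropped_names) != ("a_copy" in dropped_names)
        assert "|r|=1.000" in rep.dropped[0][1]

    def test_vif_matches_independent_regression(self, rng):
        g = metric_grid(40)
        a = rng.normal(size=g.shape)
        b = rng.normal(size=g.shape)
        c = a + b + rng.normal(scale=0.5, size=g.shape)
        stack = EnvStack(g, {"a": a, "b": b, "c": c})
        pts = self._points(g, rng, 400)
        # oracle: R^2 of c ~ a + b by explicit normal equations at the points
        df = stack.values_at(*pts).dropna()
        X = np.column_stack([np.ones(len(df)), df["a"], df["b"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["c"])
        resid = df["c"] - X @ beta
        r2 = 1 - (resid**2).sum() / ((df["c"] - df["c"].mean()) ** 2).sum()
        rep = vif_correlation_select(stack, pts, r_threshold=0.95, vif_threshold=50.0)
        assert rep.vif["c"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)

    def test_all_identical_keeps_exactly_one(self, rng):
        g = metric_grid(30)
        a = rng.normal(size=g.shape)
        stack = EnvStack(g, {"a": a, "b": a.copy(), "c": a.copy()})
        rep = vif_correlation_select(stack, self._points(g, rng))
        assert len(rep.kept) == 1
        assert len(rep.dropped) == 2

    def test_selection_order_independent(self, rng):
        g = metric_grid(30)
        layers = {f"v{i}": rng.normal(size=g.shape) for i in range(4)}
        layers["dup"] = layers["v0"] + rng.normal(scale=0.01, size=g.shape)
        pts = self._points(g, rng)
        kept1 = set(vif_correlation_select(EnvStack(g, layers), pts).kept)
        reordered = {k: layers[k] for k in reversed(list(layers))}
        kept2 = set(vif_correlation_select(EnvStack(g, reordered), pts).kept)
        assert kept1 == kept2


class TestMantelCorrelogram:
    def test_env_function_of_coordinates_maximal_concordance(self, rng):
        n = 40
        x = rng.uniform(0, 1000, n)
        y = rng.uniform(0, 1000, n)
        env = np.column_stack([x / 100.0, y / 100.0])  # exact coordinate function
        res = mantel_correlogram(
            (x, y), env, class_width=250.0, max_distance=1500.0,
            n_permutations=99, seed=0,
        )
        assert res.r_per_class[0] > 0
        assert res.p_per_class[0] == pytest.approx(1.0 / 100.0)

    def test_zero_permutations_rejected(self, rng):
        x = rng.uniform(0, 100, 12)
        with pytest.raises(ValueError):
            mantel_correlogram((x, x), np.ones((12, 1)), n_permutations=0)

    def test_sparse_class_flagged_not_error(self, rng):
        # points clustered within 10 m: distant classes have < 2 pairs
        x = rng.uniform(0, 10, 12)
        y = rng.uniform(0, 10, 12)
        env = rng.normal(size=(12, 2))
        res = mantel_correlogram(
            (x, y), env, class_width=100.0, max_distance=500.0,
            n_permutations=19, seed=1,
        )
        assert len(res.flagged) >= 1
        assert np.isnan(res.r_per_class[res.flagged[-1]])

    def test_deterministic_under_seed(self, rng):
        x = rng.uniform(0, 500, 25)
        y = rng.uniform(0, 500, 25)
        env = rng.normal(size=(25, 3))
        a = mantel_correlogram((x, y), env, n_permutations=49, seed=9)
        b = mantel_correlogram((x, y), env, n_permutations=49, seed=9)
        np.testing.assert_array_equal(a.p_per_class, b.p_per_class)


class TestFilterRecords:
    def test_dedup_and_land_rules(self):
        g = metric_grid(4, cell=100.0)
        land = np.ones(g.shape, dtype=bool)
        land[0, 0] = False
        x = [50.0, 50.0, 150.0, 155.0, 155.0, 50.0]
        y = [350.0, 350.0, 250.0, 250.0, 250.0, 250.0]
        src = ["monitoring"] * 5 + ["aggregator"]
        occ = OccurrenceSet.from_arrays(x, y, source=np.array(src, dtype=object))
        out, rep = filter_records(occ, g, land)
        assert rep["input"] == 6
        assert rep["exact_duplicates"] == 2  # (50,350) and (155,250) repeats
        assert rep["off_land"] == 1  # (50,350) lies on the masked cell
        # (150,250) and (155,250) share cell+source -> one kept
        assert rep["cell_source_duplicates"] == 1
        assert rep["kept"] == 2
        assert len(out) == 2
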