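import dataclasses

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import chisquare, pearsonr, spearmanr

from maxampo.grid import EnvStack, Grid
from maxampo.synthetic_island import (
    _CONE_RADIUS_FRACTION,
    GCM_LABELS,
    LANDCOVER_BANDS,
    SSP_LABELS,
    SyntheticIslandConfig,
    SyntheticTruth,
    default_shift_table,
    generate_climate_layers,
    generate_dem,
    generate_landcover,
    perturb_future,
    sample_presences,
    simulate_island,
    true_suitability,
)

CFG = SyntheticIslandConfig(n_rows=64, n_cols=64, n_presence=100, seed=3)
NOISELESS = dataclasses.replace(CFG, noise_sd=0.0)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_rows": 8},
            {"cell_size": 0.0},
            {"n_presence": 5},
            {"noise_sd": -1.0},
            {"true_coefficients": (0.0, 1.0)},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            dataclasses.replace(CFG, **kwargs)


class TestDem:
    def test_noiseless_cone_decreases_with_distance(self):
        dem, grid = generate_dem(NOISELESS)
        cr = (NOISELESS.n_rows - 1) / 2
        cc = (NOISELESS.n_cols - 1) / 2
        rows, cols = np.nonzero(np.isfinite(dem))
        r = np.hypot(rows - cr, cols - cc)
        order = np.argsort(r)
        # strictly decreasing elevation with radial distance (ties only at
        # exactly equal radii)
        z = dem[rows[order], cols[order]]
        rr = r[order]
        for i in range(1, len(z)):
            if rr[i] > rr[i - 1]:
                assert z[i] < z[i - 1]

    def test_deterministic(self):
        d1, _ = generate_dem(CFG)
        d2, _ = generate_dem(CFG)
        np.testing.assert_array_equal(d1, d2)

    def test_land_fraction_matches_brute_force_cone(self):
        # independent recomputation of the noiseless cone + sea thresholding
        dem, _ = generate_dem(NOISELESS)
        cs = NOISELESS.cell_size
        radius = _CONE_RADIUS_FRACTION * 64 * cs
        n_land = 0
        for i in range(64):
            for j in range(64):
                d = np.hypot(i - 31.5, j - 31.5) * cs
                if NOISELESS.peak_elevation * (1 - d / radius) > 0:
                    n_land += 1
        assert np.isfinite(dem).sum() == n_land

    def test_land_is_one_connected_component(self):
        dem, _ = generate_dem(CFG)
        _, n = ndimage.label(np.isfinite(dem))
        assert n == 1

    def test_max_elevation_within_5pct_of_peak(self):
        dem, _ = generate_dem(CFG)
        assert abs(np.nanmax(dem) - CFG.peak_elevation) <= 0.05 * CFG.peak_elevation

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="16"):
            SyntheticIslandConfig(n_rows=12, n_cols=64)


class TestClimate:
    def test_noiseless_layer_is_affine_in_elevation(self):
        dem, grid = generate_dem(NOISELESS)
        stack = generate_climate_layers(dem, grid, NOISELESS)
        land = np.isfinite(dem)
        for name in stack.names:
            coeffs = np.polyfit(dem[land], stack[name][land], 1)
            resid = stack[name][land] - np.polyval(coeffs, dem[land])
            assert np.max(np.abs(resid)) < 1e-9

    def test_unsmoothed_noise_variance_matches_noise_sd(self):
        cfg = dataclasses.replace(CFG, smoothing_radius=0, noise_sd=3.0)
        dem, grid = generate_dem(dataclasses.replace(cfg, noise_sd=0.0))
        noisy = generate_climate_layers(dem, grid, cfg)
        clean = generate_climate_layers(dem, grid, dataclasses.replace(cfg, noise_sd=0.0))
        land = np.isfinite(dem)
        assert land.sum() > 1000
        resid = (noisy["clim01"] - clean["clim01"])[land]
        # sample variance of >1000 iid N(0, 9) cells
        assert resid.var() == pytest.approx(9.0, rel=0.15)

    def test_layers_have_independent_noise(self):
        cfg = dataclasses.replace(
            CFG, n_rows=128, n_cols=128, smoothing_radius=0, noise_sd=5.0
        )
        dem, grid = generate_dem(dataclasses.replace(cfg, noise_sd=0.0))
        noisy = generate_climate_layers(dem, grid, cfg)
        clean = generate_climate_layers(dem, grid, dataclasses.replace(cfg, noise_sd=0.0))
        land = np.isfinite(dem)
        r1 = (noisy["clim01"] - clean["clim01"])[land]
        r2 = (noisy["clim02"] - clean["clim02"])[land]
        assert abs(pearsonr(r1, r2).statistic) < 0.2

    def test_grid_coherence(self):
        dem, grid = generate_dem(CFG)
        stack = generate_climate_layers(dem, grid, CFG)
        assert stack.grid.same_geometry(grid)
        for name in stack.names:
            np.testing.assert_array_equal(
                np.isfinite(stack[name]), np.isfinite(dem)
            )


class TestLandcover:
    def test_flat_dem_single_class(self):
        grid = Grid(n_rows=30, n_cols=30, cell_size=100.0, origin=(0, 3000))
        dem = np.full(grid.shape, 600.0)
        lc, lc_grid = generate_landcover(dem, grid, CFG)
        assert lc_grid.shape == (10, 10)
        assert np.unique(lc).size == 1

    def test_codes_in_declared_set(self):
        dem, grid = generate_dem(CFG)
        lc, _ = generate_landcover(dem, grid, CFG)
        codes = set(np.unique(lc[np.isfinite(lc)]).astype(int))
        assert codes <= {code for _, code in LANDCOVER_BANDS}

    def test_banding_matches_brute_force(self):
        dem, grid = generate_dem(CFG)
        lc, lc_grid = generate_landcover(dem, grid, CFG)
        # independent recomputation: per coarse cell, mean of land elevations
        # in its 3x3 block, then highest band whose lower edge is <= mean
        for i in range(lc_grid.n_rows):
            for j in range(lc_grid.n_cols):
                block = dem[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
                vals = block[np.isfinite(block)]
                if vals.size == 0:
                    assert np.isnan(lc[i, j])
                    continue
                mean = vals.mean()
                expected = None
                for lower, code in LANDCOVER_BANDS:
                    if mean >= lower:
                        expected = code
                assert lc[i, j] == expected


class TestSuitability:
    def test_zero_coefficients_give_half(self):
        dem, grid = generate_dem(CFG)
        stack = generate_climate_layers(dem, grid, CFG)
        suit = true_suitability(stack, (0.0, 0.0, 0.0, 0.0, 0.0))
        land = np.isfinite(dem)
        np.testing.assert_allclose(suit[land], 0.5)
        assert np.all(np.isnan(suit[~land]))

    def test_large_negative_intercept_drives_to_zero(self):
        dem, grid = generate_dem(CFG)
        stack = generate_climate_layers(dem, grid, CFG)
        suit = true_suitability(stack, (-30.0, 0.0, 0.0, 0.0, 0.0))
        assert np.nanmax(suit) < 1e-10

    def test_single_coefficient_monotone_in_layer(self):
        dem, grid = generate_dem(CFG)
        stack = generate_climate_layers(dem, grid, CFG)
        suit = true_suitability(stack, (0.0, 0.0, 0.0, 2.0, 0.0))
        land = np.isfinite(dem)
        rho = spearmanr(stack["clim03"][land], suit[land]).statistic
        assert rho == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        dem, grid = generate_dem(CFG)
        stack = generate_climate_layers(dem, grid, CFG)
        with pytest.raises(ValueError):
            true_suitability(stack, (0.0, 1.0))


class TestPresences:
    def test_uniform_suitability_gives_uniform_cells(self):
        grid = Grid(n_rows=20, n_cols=20, cell_size=100.0, origin=(0, 2000))
        suit = np.full(grid.shape, 0.7)
        occ = sample_presences(suit, grid, 5000, seed=11, dedupe=False)
        counts = np.bincount(occ.meta["drawn_cells"], minlength=400)
        assert chisquare(counts).pvalue > 0.01

    def test_point_mass(self):
        grid = Grid(n_rows=20, n_cols=20, cell_size=100.0, origin=(0, 2000))
        suit = np.zeros(grid.shape)
        suit[5, 7] = 1.0
        occ = sample_presences(suit, grid, 50, seed=1, dedupe=False)
        x, y = grid.cell_centre(5, 7)
        assert np.all(occ.x == x) and np.all(occ.y == y)
        assert occ.meta["n_drawn"] == 50 and occ.meta["n_unique"] == 1

    def test_deterministic(self):
        dem, grid = generate_dem(CFG)
        stack = generate_climate_layers(dem, grid, CFG)
        suit = true_suitability(stack, CFG.true_coefficients)
        a = sample_presences(suit, grid, 100, seed=5)
        b = sample_presences(suit, grid, 100, seed=5)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_too_many_points_rejected(self):
        grid = Grid(n_rows=20, n_cols=20, cell_size=100.0, origin=(0, 2000))
        suit = np.zeros(grid.shape)
        suit[0, :5] = 1.0
        with pytest.raises(ValueError, match="positive suitability"):
            sample_presences(suit, grid, 10, seed=1)

    def test_presences_fall_on_land(self):
        island = simulate_island(CFG)
        r, c = island.truth.presence_points.cells_on(island.grid)
        assert np.all(np.isfinite(island.dem[r, c]))


class TestFutureScenarios:
    def _stack(self):
        dem, grid = generate_dem(CFG)
        return generate_climate_layers(dem, grid, CFG)

    def test_zero_shift_is_identity(self):
        stack = self._stack()
        table = {("s", "g"): {n: ("add", 0.0) for n in stack.names}}
        out = perturb_future(stack, "s", "g", table)
        for n in stack.names:
            np.testing.assert_array_equal(out[n], stack[n])

    def test_additive_shift_exact(self):
        stack = self._stack()
        table = {("s", "g"): {"clim01": ("add", 2.5)}}
        out = perturb_future(stack, "s", "g", table)
        land = np.isfinite(stack["clim01"])
        np.testing.assert_allclose(
            out["clim01"][land] - stack["clim01"][land], 2.5
        )
        # layers without a shift row stay untouched
        np.testing.assert_array_equal(out["clim02"], stack["clim02"])

    def test_default_table_enumerates_15_scenarios(self):
        table = default_shift_table(CFG.climate_names())
        assert len(table) == 15
        assert {k[0] for k in table} == set(SSP_LABELS)
        assert {k[1] for k in table} == set(GCM_LABELS)

    def test_unknown_label_rejected(self):
        stack = self._stack()
        table = default_shift_table(CFG.climate_names())
        with pytest.raises(KeyError, match="unknown scenario"):
            perturb_future(stack, "ssp999", "IPSL", table)


class TestTruthSidecar:
    def test_round_trip(self, tmp_path, small_island):
        p = tmp_path / "truth.txt"
        small_island.truth.write_sidecar(p)
        back = SyntheticTruth.read_sidecar(p)
        assert back["coefficients"] == small_island.truth.coefficients
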