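"""Gridded yield maps: per-cell runs, optimal ecotype, masking, totals."""

import numpy as np
import pytest

from switchfor import (aggregate_totals, apply_mask, generate_grid,
                       genotype_defaults, optimal_map, preset, run_grid)
from switchfor.spatial import ECOTYPE_CODES, YieldRaster, cell_areas_ha


def make_raster(values, lat0=36.0, d=0.25, ecotype=None):
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape
    return YieldRaster(values=values,
                       lat=lat0 - d * np.arange(ny),
                       lon=107.0 + d * np.arange(nx),
                       ecotype=ecotype, cell_degrees=d)


@pytest.fixture(scope="module")
def uniform_cube():
    return generate_grid(1, 1, preset("warm-humid"), years=3, seed=21)


class TestRunGrid:
    def test_uniform_cube_matches_single_site(self, uniform_cube, site,
                                              loam):
        """A 1x1 grid reproduces the run_site yield on the same forcing."""
        import pandas as pd
        from switchfor import SiteInfo, run_site
        raster = run_grid(uniform_cube, genotype_defaults("lowland"))
        weather = pd.DataFrame({
            "date": pd.DatetimeIndex(uniform_cube["time"].values),
            "tmin": uniform_cube["tmin"].values[:, 0, 0],
            "tmax": uniform_cube["tmax"].values[:, 0, 0],
            "precip": uniform_cube["precip"].values[:, 0, 0],
            "solar": uniform_cube["solar"].values[:, 0, 0]})
        ref = run_site(weather,
                       SiteInfo(latitude=float(uniform_cube["lat"][0])),
                       loam, genotype_defaults("lowland"))
        assert raster.values[0, 0] == pytest.approx(
            float(ref.annual["harvest_yield"].mean()), rel=1e-9)

    def test_lethal_winters_are_nodata(self):
        cube = generate_grid(1, 1, preset("cold-continental"), years=3,
                             seed=8, base_latitude=40.0)
        killed = run_grid(cube, genotype_defaults("lowland"))
        assert np.isnan(killed.values[0, 0])
        survivor = run_grid(cube, genotype_defaults("upland"))
        assert survivor.values[0, 0] > 0.0

    def test_missing_layers_rejected(self, uniform_cube):
        with pytest.raises(ValueError, match="missing layers"):
            run_grid(uniform_cube.drop_vars("sand"),
                     genotype_defaults("upland"))


class TestOptimalMap:
    def test_cellwise_max_with_nodata_passthrough(self):
        up = make_raster([[5.0, np.nan]])
        low = make_raster([[20.0, 10.0]])
        best = optimal_map(up, low)
        np.testing.assert_allclose(best.values, [[20.0, 10.0]])
        assert np.all(best.ecotype == ECOTYPE_CODES["lowland"])

    def test_ties_go_to_upland(self):
        up = make_raster([[8.0]])
        low = make_raster([[8.0]])
        assert optimal_map(up, low).ecotype[0, 0] \
            == ECOTYPE_CODES["upland"]

    def test_matches_brute_force_on_random_rasters(self):
        """50x50 random pair with NoData equals a per-cell python loop."""
        rng = np.random.default_rng(17)
        shape = (50, 50)
        up = rng.uniform(0, 15, shape)
        low = rng.uniform(0, 30, shape)
        up[rng.random(shape) < 0.2] = np.nan
        low[rng.random(shape) < 0.3] = np.nan
        best = optimal_map(make_raster(up), make_raster(low))
        for j in range(shape[0]):
            for i in range(shape[1]):
                u, l = up[j, i], low[j, i]
                if np.isnan(u) and np.isnan(l):
                    assert np.isnan(best.values[j, i])
                else:
                    expected = np.nanmax([u, l])
                    assert best.values[j, i] == expected
        # cellwise max dominates both single-ecotype totals
        area = 100.0
        t_best = aggregate_totals(best, cell_area_ha=area)["total_tg"]
        t_up = aggregate_totals(make_raster(up),
                                cell_area_ha=area)["total_tg"]
        t_low = aggregate_totals(make_raster(low),
                                 cell_area_ha=area)["total_tg"]
        assert t_best >= max(t_up, t_low)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="co-registered"):
            optimal_map(make_raster(np.ones((2, 2))),
                        make_raster(np.ones((3, 2))))


class TestMask:
    def test_slope_limit_is_strict_inequality(self):
        r = make_raster([[10.0, 10.0]])
        slope = np.array([[15.0, 15.1]])
        masked = apply_mask(r, np.ones((1, 2)), slope, slope_limit=15.0)
        assert masked.values[0, 0] == 10.0
        assert np.isnan(masked.values[0, 1])

    def test_empty_mask_blanks_everything(self):
        r = make_raster(np.full((3, 3), 7.0))
        masked = apply_mask(r, np.zeros((3, 3)))
        assert np.all(np.isnan(masked.values))

    def test_full_mask_flat_terrain_is_identity(self):
        r = make_raster(np.full((3, 3), 7.0))
        masked = apply_mask(r, np.ones((3, 3)), np.zeros((3, 3)))
        np.testing.assert_allclose(masked.values, r.values)

    def test_masking_never_increases_totals(self):
        rng = np.random.default_rng(3)
        r = make_raster(rng.uniform(0, 25, (10, 10)))
        mask = rng.random((10, 10)) < 0.5
        t_all = aggregate_totals(r, cell_area_ha=100.0)["total_tg"]
        t_masked = aggregate_totals(apply_mask(r, mask),
                                    cell_area_ha=100.0)["total_tg"]
        assert t_masked <= t_all


class TestTotals:
    def test_single_cell_arithmetic(self):
        r = make_raster([[20.0]])
        out = aggregate_totals(r, cell_area_ha=100.0)
        assert out["total_tg"] == pytest.approx(0.002)
        assert out["weighted_mean"] == pytest.approx(20.0)
        assert out["area_mha"] == pytest.approx(1e-4)

    def test_all_nodata(self):
        out = aggregate_totals(make_raster(np.full((2, 2), np.nan)),
                               cell_area_ha=100.0)
        assert out["total_tg"] == 0.0
        assert out["n_cells"] == 0
        assert np.isnan(out["weighted_mean"])

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 30, (8, 8))
        vals[rng.random((8, 8)) < 0.25] = np.nan
        r = make_raster(vals)
        areas = cell_areas_ha(r)
        out = aggregate_totals(r)
        total = 0.0
        area = 0.0
        for j in range(8):
            for i in range(8):
                if not np.isnan(vals[j, i]):
                    total += vals[j, i] * areas[j, i]
                    area += areas[j, i]
        assert out["total_tg"] == pytest.approx(total * 1e-6, rel=1e-12)
        assert out["weighted_mean"] == pytest.approx(total / area,
                                                     rel=1e-12)

    def test_cosine_rule_cell_area_hand_check(self):
        """0.25-degree cell at 36 N: (0.25 x 111.19 km)^2 cos(36)."""
        r = make_raster([[1.0]], lat0=36.0, d=0.25)
        km_per_deg = np.pi * 6371.0 / 180.0
        expected = (0.25 * km_per_deg) ** 2 * np.cos(np.deg2rad(36.0)) * 100
        assert cell_areas_ha(r)[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_aggregation_permutation_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 20, (4, 4))
        a = aggregate_totals(make_raster(vals), cell_area_ha=50.0)
        b = aggregate_totals(make_raster(rng.permutation(vals.ravel())
                                         .reshape(4, 4)),
                             cell_area_ha=50.0)
        assert a["total_tg"] == pytest.approx(b["total_tg"])
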