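import math

import numpy as np
import pytest
from scipy.stats import norm

from adaptscape import (
    ClimatePair,
    Grid,
    InvalidParameterError,
    build_kernel,
    compute_area,
    compute_climate_area_velocity,
    compute_elev_range,
    compute_lat_range,
    compute_relief_hydro,
    simulate_climate_space_retention,
)

from conftest import random_grid
from oracles import brute_relief_hydro, brute_velocity


def all_true(shape):
    return np.ones(shape, bool)


class TestArea:
    def test_radius0_all_target_equals_cell_area(self, rng):
        g = random_grid(rng, 4, 4)
        g.nodata[:] = False
        out = compute_area(g, all_true((4, 4)), build_kernel(0))
        assert (out.values == 1.0).all()

    def test_interior_cell_r3_is_29_km2(self, rng):
        g = random_grid(rng, 9, 9)
        g.nodata[:] = False
        out = compute_area(g, all_true((9, 9)), build_kernel(3))
        assert out.values[4, 4] == 29.0

    def test_scales_with_cell_area(self, rng):
        g = random_grid(rng, 9, 9, cell_km=2.0)
        g.nodata[:] = False
        out = compute_area(g, all_true((9, 9)), build_kernel(6.0, cell_km=2.0))
        assert out.values[4, 4] == 29.0 * 4.0


class TestLatRange:
    def test_radius0_is_zero(self, rng):
        g = random_grid(rng, 5, 5)
        g.nodata[:] = False
        out = compute_lat_range(g.like(np.broadcast_to(
            g.row_latitudes[:, None], (5, 5)).copy()), all_true((5, 5)), build_kernel(0))
        assert (out.values == 0).all()

    def test_r3_interior_spans_rows_within_kernel(self):
        # rows at 40.00, 40.01, ... 40.09: an interior cell at radius 3
        # sees rows +-3 → latitudinal range 0.06 degrees
        lats = 40.0 + 0.01 * np.arange(10)
        lat2d = np.broadcast_to(lats[:, None], (10, 10)).copy()
        g = Grid(lat2d, nodata=np.zeros((10, 10), bool), row_latitudes=lats)
        out = compute_lat_range(g, all_true((10, 10)), build_kernel(3))
        assert out.values[5, 5] == pytest.approx(0.06, abs=1e-12)

    def test_constant_latitude_gives_zero(self):
        lat2d = np.full((1, 8), 12.0)
        g = Grid(lat2d, nodata=np.zeros((1, 8), bool), row_latitudes=np.array([12.0]))
        out = compute_lat_range(g, all_true((1, 8)), build_kernel(2))
        assert (out.values == 0).all()


class TestElevRange:
    def test_flat_terrain_and_radius0_are_zero(self, rng):
        flat = Grid(np.full((6, 6), 250.0))
        assert (compute_elev_range(flat, all_true((6, 6)), build_kernel(2)).values == 0).all()
        g = random_grid(rng, 6, 6)
        g.nodata[:] = False
        assert (compute_elev_range(g, all_true((6, 6)), build_kernel(0)).values == 0).all()


class TestReliefHydro:
    def test_flat_terrain_gives_zero(self, rng):
        flat = Grid(np.full((7, 7), 100.0))
        hydro = rng.random((7, 7)) < 0.5
        out = compute_relief_hydro(flat, hydro, all_true((7, 7)), build_kernel(2))
        assert (out.values == 0).all()

    def test_no_hydro_cells_gives_zero(self, rng):
        g = random_grid(rng, 7, 7)
        g.nodata[:] = False
        out = compute_relief_hydro(g, np.zeros((7, 7), bool), all_true((7, 7)),
                                   build_kernel(2))
        assert (out.values == 0).all()

    def test_direct_evaluation_of_relief_sum(self):
        # window with hydro cells at 100, 150, 200 m and window minimum 90 m
        # → (10 + 60 + 110) = 180
        e = np.full((5, 5), 300.0)
        e[2, 2] = 90.0
        e[1, 1], e[1, 3], e[3, 2] = 100.0, 150.0, 200.0
        hydro = np.zeros((5, 5), bool)
        hydro[1, 1] = hydro[1, 3] = hydro[3, 2] = True
        g = Grid(e, nodata=np.zeros((5, 5), bool))
        out = compute_relief_hydro(g, hydro, all_true((5, 5)), build_kernel(2))
        assert out.values[2, 2] == pytest.approx(180.0)

    def test_matches_brute_force_oracle(self, rng):
        g = random_grid(rng, 10, 10, nodata_frac=0.1)
        hydro = rng.random((10, 10)) < 0.4
        target = rng.random((10, 10)) < 0.7
        k = build_kernel(2)
        out = compute_relief_hydro(g, hydro, target, k)
        ref, empty = brute_relief_hydro(g.values, hydro, target & ~g.nodata, k, 1.0)
        assert np.array_equal(out.nodata, empty)
        assert np.array_equal(out.values[~empty], ref[~empty])


class TestClimateAreaVelocity:
    def pair(self, now, future, years=1.0):
        return ClimatePair(Grid(now), Grid(future), years)

    def test_uniform_climate_hits_the_floor(self):
        # spatially uniform baseline: sigma = 0, so V = rate / 0.1
        now = np.full((6, 6), 15.0)
        future = now + 0.05 * 95.0
        pair = self.pair(now, future, years=95.0)
        out = compute_climate_area_velocity(pair, all_true((6, 6)), build_kernel(2))
        np.testing.assert_allclose(out.values, 0.5, rtol=1e-12)

    def test_direct_evaluation_with_known_sigma(self):
        # baseline {10..14} °C in the window (population sigma = sqrt 2),
        # uniform rate 0.04 °C/yr → V = 0.04 / (sqrt 2 + 0.1)
        now = np.tile(np.array([10.0, 11.0, 12.0, 13.0, 14.0]), (5, 1))
        future = now + 0.04
        pair = self.pair(now, future, years=1.0)
        # target only the middle row, kernel wide enough to span it
        target = np.zeros((5, 5), bool)
        target[2, :] = True
        out = compute_climate_area_velocity(pair, target, build_kernel(2))
        expected = 0.04 / (math.sqrt(2.0) + 0.1)
        assert out.values[2, 2] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.0264164, abs=5e-7)

    def test_no_change_gives_zero(self, rng):
        now = rng.normal(10, 3, (6, 6))
        pair = self.pair(now, now.copy())
        out = compute_climate_area_velocity(pair, all_true((6, 6)), build_kernel(2))
        assert (out.values == 0).all()

    def test_matches_brute_force_oracle(self, rng):
        now = random_grid(rng, 9, 9, nodata_frac=0.05)
        future = now.like(now.values + rng.normal(1.0, 0.5, (9, 9)),
                          nodata=now.nodata.copy())
        pair = ClimatePair(now, future, 20.0)
        target = rng.random((9, 9)) < 0.7
        k = build_kernel(2)
        out = compute_climate_area_velocity(pair, target, k)
        ref, empty = brute_velocity(now.values, future.values, 20.0,
                                    target & ~now.nodata, k, 0.1)
        assert np.array_equal(out.nodata, empty)
        assert np.array_equal(out.values[~empty], ref[~empty])

    def test_floor_free_velocity_halves_when_sigma_doubles(self):
        now = np.tile(np.linspace(0.0, 8.0, 9), (9, 1))
        wide = 2.0 * now  # doubles the spatial sd, same mean rate
        delta = np.full((9, 9), 2.0)
        k = build_kernel(3)
        target = all_true((9, 9))
        v1 = compute_climate_area_velocity(self.pair(now, now + delta), target, k,
                                           floor_constant=0.0)
        v2 = compute_climate_area_velocity(self.pair(wide, wide + delta), target, k,
                                           floor_constant=0.0)
        ok = ~v1.nodata & (v1.values > 0)
        np.testing.assert_allclose(v2.values[ok], v1.values[ok] / 2.0, rtol=1e-9)


class TestRetentionSimulation:
    def test_zero_shift_retains_almost_everything(self):
        res = simulate_climate_space_retention(0.0, 1.0, n=10_000, seed=1)
        assert abs(res.retention - 1.0) <= 0.02
        assert res.area_factor == pytest.approx(1.0 / res.retention)
        assert res.area_factor_adjusted == pytest.approx(res.area_factor + 1.0)

    def test_distant_shift_retains_nothing(self):
        res = simulate_climate_space_retention(10.0, 1.0, n=2_000, seed=2)
        assert res.retention <= 0.001
        if res.retention == 0:
            assert math.isinf(res.area_factor)

    def test_agrees_with_normal_cdf_oracle(self):
        n, seed = 100_000, 7
        res = simulate_climate_space_retention(1.0, 1.0, n=n, seed=seed)
        # replay the generator to recover the realized current-sample extremes
        rng = np.random.default_rng(seed)
        current = rng.normal(0.0, 1.0, n)
        lo, hi = current.min(), current.max()
        expected = norm.cdf(hi - 1.0) - norm.cdf(lo - 1.0)
        assert abs(res.retention - expected) <= 0.01

    @pytest.mark.parametrize("kw", [dict(mean_shift=0, sd=0.0), dict(mean_shift=0, sd=1, n=1)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            simulate_climate_space_retention(**kw)
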