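import numpy as np
import pytest

from adaptscape import (
    Grid,
    InvalidParameterError,
    Landscape,
    ScenarioSpec,
    area_to_radius,
    build_kernel,
    comparison_factor,
    partner_composition,
    partnership_percentiles,
    run_scenario,
    scenario_means,
)
from adaptscape.errors import EmptyDomainError

from oracles import brute_focal


def make_landscape(elev, pa_ids, hydro=None, t_rate=0.05, p_rate=0.4,
                   years=100.0, lats=None):
    nr, nc = elev.shape
    if hydro is None:
        hydro = np.zeros((nr, nc), bool)
    if lats is None:
        lats = 40.0 - 0.01 * np.arange(nr)
    nodata = np.zeros((nr, nc), bool)

    def grid(v):
        return Grid(np.asarray(v, float), nodata=nodata.copy(), row_latitudes=lats)

    t_now = 20.0 - 0.006 * elev
    p_now = 700.0 + 0.3 * elev
    return Landscape(
        elevation=grid(elev), hydro=hydro, pa_ids=pa_ids,
        t_now=grid(t_now), t_future=grid(t_now + t_rate * years),
        p_now=grid(p_now), p_future=grid(p_now + p_rate * years),
        years_elapsed=years,
    )


@pytest.fixture
def rect_pa_landscape(rng):
    """One rectangular PA on bumpy terrain with a hydro stripe."""
    elev = rng.uniform(0, 500, (10, 12))
    pa = np.zeros((10, 12), np.int64)
    pa[2:6, 3:8] = 1
    hydro = np.zeros((10, 12), bool)
    hydro[4, :] = True
    return make_landscape(elev, pa, hydro=hydro)


class TestScenarioSpec:
    def test_partnership_modes_need_positive_radius(self):
        with pytest.raises(InvalidParameterError):
            ScenarioSpec("pa_partnership", 0.0)
        ScenarioSpec("pixel_null")  # radius ignored

    def test_unknown_mode_rejected(self):
        with pytest.raises(InvalidParameterError):
            ScenarioSpec("solo")


class TestNullModels:
    def test_pixel_null_limits(self, rect_pa_landscape):
        ind = run_scenario(rect_pa_landscape, ScenarioSpec("pixel_null"))
        land = rect_pa_landscape.land_mask
        assert (ind.area.values[land] == 1.0).all()
        assert (ind.lat_range.values[land] == 0.0).all()
        assert (ind.elev_range.values[land] == 0.0).all()
        assert (ind.relief_hydro.values[land] == 0.0).all()
        np.testing.assert_allclose(ind.velocity_t.values[land], 0.05 / 0.1, rtol=1e-12)
        np.testing.assert_allclose(ind.velocity_p.values[land], 0.4 / 0.1, rtol=1e-12)

    def test_pa_null_equals_whole_pa_reduction(self, rect_pa_landscape):
        ls = rect_pa_landscape
        ind = run_scenario(ls, ScenarioSpec("pa_null"))
        sel = ls.pa_ids == 1
        e = ls.elevation.values[sel]
        assert np.allclose(ind.area.values[sel], sel.sum() * 1.0)
        assert np.allclose(ind.elev_range.values[sel], e.max() - e.min())
        lat2d = ls.latitude_grid.values[sel]
        assert np.allclose(ind.lat_range.values[sel], lat2d.max() - lat2d.min())
        expected_h = float((ls.elevation.values[sel & ls.hydro] - e.min()).sum())
        assert np.allclose(ind.relief_hydro.values[sel], expected_h)
        rate = (ls.t_future.values - ls.t_now.values)[sel] / ls.years_elapsed
        expected_v = abs(rate.mean()) / (ls.t_now.values[sel].std() + 0.1)
        assert np.allclose(ind.velocity_t.values[sel], expected_v)
        assert ind.area.nodata[0, 0]  # non-PA cells carry no value

    def test_pa_modes_require_pa_cells(self, rng):
        ls = make_landscape(rng.uniform(0, 100, (6, 6)), np.zeros((6, 6), np.int64))
        with pytest.raises(EmptyDomainError):
            run_scenario(ls, ScenarioSpec("pa_null"))
        with pytest.raises(EmptyDomainError):
            run_scenario(ls, ScenarioSpec("pa_partnership", 3.0))


class TestDominance:
    def test_target_superset_and_null_ordering_for_area(self, rect_pa_landscape):
        ls = rect_pa_landscape
        r = 3.0
        a_pa = run_scenario(ls, ScenarioSpec("pa_partnership", r)).area
        a_all = run_scenario(ls, ScenarioSpec("pa_nonpa_partnership", r)).area
        a_null = run_scenario(ls, ScenarioSpec("pixel_null")).area
        on = ~a_pa.nodata
        assert (a_all.values[on] >= a_pa.values[on]).all()
        assert (a_pa.values[on] >= a_null.values[on]).all()

    def test_scenario_means_restricted_to_pa_domain(self, rect_pa_landscape):
        ind = run_scenario(rect_pa_landscape, ScenarioSpec("pixel_null"))
        means = scenario_means(ind, domain=rect_pa_landscape.pa_mask)
        assert means["area"] == pytest.approx(1.0)


class TestComparisonFactor:
    @pytest.mark.parametrize("a,b,expected", [
        (2.0, 1.0, 2.0),
        (1.0, 1.0, 1.0),
        (0.4, 0.6, -1.5),  # a decrease by x prints -x
    ])
    def test_sign_convention(self, a, b, expected):
        assert comparison_factor(a, b).value == pytest.approx(expected)

    def test_magnitude_at_least_one(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0.01, 10, 2)
            assert abs(comparison_factor(a, b).value) >= 1.0

    def test_non_positive_means_rejected(self):
        with pytest.raises(InvalidParameterError):
            comparison_factor(0.0, 1.0)


class TestPartnerComposition:
    def test_all_pa_landscape_is_100_percent(self, rng):
        ids = np.ones((8, 8), np.int64)
        ls = make_landscape(rng.uniform(0, 100, (8, 8)), ids)
        pct, summary = partner_composition(ls, build_kernel(2))
        assert np.allclose(pct.values[~pct.nodata], 100.0)
        pa_row = summary[summary.focal_class == "pa"].iloc[0]
        assert pa_row.mean_pct_pa_partners == pytest.approx(100.0)
        assert pa_row.pct_cells_gt50 == pytest.approx(100.0)

    def test_pa_free_landscape_is_0_percent(self, rng):
        ls = make_landscape(rng.uniform(0, 100, (8, 8)), np.zeros((8, 8), np.int64))
        pct, summary = partner_composition(ls, build_kernel(2))
        assert np.allclose(pct.values[~pct.nodata], 0.0)
        row = summary[summary.focal_class == "non_pa"].iloc[0]
        assert row.mean_pct_pa_partners == pytest.approx(0.0)

    def test_per_cell_values_match_brute_force_counts(self, rng):
        ids = (rng.random((9, 9)) < 0.3).astype(np.int64)
        ls = make_landscape(rng.uniform(0, 100, (9, 9)), ids)
        k = build_kernel(2)
        pct, _ = partner_composition(ls, k)
        n_pa, _ = brute_focal(ids.astype(float), ids > 0, k, "count")
        n_land, _ = brute_focal(ids.astype(float), np.ones((9, 9), bool), k, "count")
        expected = 100.0 * n_pa / n_land
        np.testing.assert_allclose(pct.values, expected, rtol=1e-12)
        assert pct.values.min() >= 0.0 and pct.values.max() <= 100.0


class TestPartnershipScales:
    def test_single_entry_percentiles_collapse(self):
        assert partnership_percentiles([42.0]) == (42.0, 42.0, 42.0)

    def test_symmetric_table_median(self):
        p5, p50, p95 = partnership_percentiles(list(range(1, 101)))
        assert p50 == pytest.approx(50.5)

    def test_matches_sorted_interpolation_oracle(self, rng):
        areas = rng.uniform(10, 1e6, 37)
        p5, p50, p95 = partnership_percentiles(areas)
        s = np.sort(areas)

        def interp(q):
            pos = q / 100 * (len(s) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            hi = min(lo + 1, len(s) - 1)
            return s[lo] * (1 - frac) + s[hi] * frac

        assert p5 == pytest.approx(interp(5))
        assert p50 == pytest.approx(interp(50))
        assert p95 == pytest.approx(interp(95))

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidParameterError):
            partnership_percentiles([])


class TestAreaToRadius:
    def test_printed_partnership_percentile_radius(self):
        assert area_to_radius(3.3e4, rounded=True) == 102.0

    def test_unit_circle(self):
        assert area_to_radius(np.pi) == pytest.approx(1.0)

    def test_inverse_of_circle_area(self, rng):
        for r in rng.uniform(0.1, 1000, 20):
            assert area_to_radius(np.pi * r * r) == pytest.approx(r, rel=1e-9)

    def test_non_positive_area_rejected(self):
        with pytest.raises(InvalidParameterError):
            area_to_radius(0.0)
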