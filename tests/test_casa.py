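"""Light-use-efficiency model: FPAR/APAR/ε factors and the NPP identity."""

import numpy as np
import pytest

from vegcarbon.casa import (CasaConfig, VegTypeParams, compute_apar,
                            compute_fpar, compute_lue, compute_npp,
                            temperature_stress, validate_npp, water_stress)
from vegcarbon.grid_io import GridStack, RasterGrid
from vegcarbon.synthetic import MonthlyClimate, generate_climate, generate_vegetation

from conftest import make_grid


CFG = CasaConfig()
FOREST = CFG.veg_table[1]


def veg_grid(shape, code=1):
    return make_grid(np.full(shape, float(code)))


class TestFpar:
    @pytest.mark.parametrize(
        "ndvi, expected",
        [
            (FOREST.ndvi_min, 0.0),                     # bare-soil boundary
            (FOREST.ndvi_max, CFG.fpar_max),            # saturation boundary
            ((FOREST.ndvi_min + FOREST.ndvi_max) / 2, CFG.fpar_max / 2),  # linear midpoint
        ],
    )
    def test_linear_in_ndvi(self, ndvi, expected):
        out = compute_fpar(make_grid(np.full((3, 3), ndvi)), veg_grid((3, 3)))
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_below_minimum_is_zero(self):
        out = compute_fpar(make_grid(np.full((2, 2), -0.1)), veg_grid((2, 2)))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_monotone_in_ndvi(self):
        ndvi = np.linspace(-0.2, 1.0, 50).reshape(1, -1)
        out = compute_fpar(make_grid(ndvi), veg_grid((1, 50)))
        assert (np.diff(out.values[0]) >= 0).all()
        assert out.values.min() >= 0 and out.values.max() <= CFG.fpar_max

    def test_unknown_vegetation_code_raises(self):
        with pytest.raises(ValueError, match="known codes"):
            compute_fpar(make_grid(np.full((2, 2), 0.5)), veg_grid((2, 2), code=42))

    def test_ndvi_out_of_range_raises(self):
        with pytest.raises(ValueError, match="NDVI"):
            compute_fpar(make_grid(np.full((2, 2), 1.5)), veg_grid((2, 2)))


class TestApar:
    def test_zero_radiation_zero_apar(self):
        out = compute_apar(make_grid(np.zeros((2, 2))), make_grid(np.full((2, 2), 0.7)))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_arithmetic(self):
        out = compute_apar(make_grid(np.full((2, 2), 400.0)),
                           make_grid(np.full((2, 2), 0.5)))
        np.testing.assert_allclose(out.values, 100.0)

    def test_bounded_by_half_sol(self):
        rng = np.random.default_rng(1)
        sol = make_grid(rng.uniform(0, 600, (10, 10)))
        fpar = make_grid(rng.uniform(0, 0.95, (10, 10)))
        out = compute_apar(sol, fpar)
        assert (out.values <= 0.5 * sol.values + 1e-12).all()

    def test_negative_sol_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_apar(make_grid(np.full((2, 2), -1.0)), make_grid(np.full((2, 2), 0.5)))


class TestStressScalars:
    def test_te1_quadratic_oracle(self):
        topt = np.array([0.0, 10.0, 20.0, 30.0])
        te1, _ = temperature_stress(np.full(4, 20.0), topt)
        np.testing.assert_allclose(te1, np.clip(0.8 + 0.02 * topt - 0.0005 * topt ** 2, 0, 1))

    def test_te1_maximal_at_20(self):
        te1, _ = temperature_stress(np.array([20.0]), np.array([20.0]))
        assert te1[0] == pytest.approx(1.0)

    def test_te2_peaks_near_optimum_and_bounded(self):
        t = np.linspace(-20, 45, 200)
        _, te2 = temperature_stress(t, np.full_like(t, 20.0))
        assert te2.max() <= 1.0
        assert abs(t[np.argmax(te2)] - 20.0) < 5.0

    def test_cold_month_strongly_stressed(self):
        te1, te2 = temperature_stress(np.array([-10.0]), np.array([22.0]))
        assert te1[0] * te2[0] < 0.5

    def test_water_stress_floor_and_saturation(self):
        w = water_stress(np.array([0.0, 60.0, 120.0, 500.0]), demand=120.0)
        np.testing.assert_allclose(w, [0.5, 0.75, 1.0, 1.0])


class TestLue:
    def _stack(self, values, sc_shape=(4, 4), months=12):
        layers = [make_grid(np.full(sc_shape, v)) for v in values[:months]]
        return GridStack(layers, time_index=[(2000, m + 1) for m in range(months)])

    def test_bounded_by_eps_max(self):
        t = self._stack(np.linspace(2, 28, 12))
        r = self._stack(np.full(12, 100.0))
        ndvi = self._stack(np.linspace(0.3, 0.8, 12))
        lue = compute_lue(t, r, ndvi, veg_grid((4, 4)))
        arr = lue.as_array()
        assert (arr >= 0).all() and (arr <= FOREST.eps_max + 1e-12).all()

    def test_water_floor_halves_lue(self):
        # dry months: Wε = 0.5 exactly, so ε = 0.5·Tε1·Tε2·εmax
        t = self._stack(np.full(12, 20.0))
        dry = self._stack(np.full(12, 0.0))
        wet = self._stack(np.full(12, 200.0))
        ndvi = self._stack(np.full(12, 0.6))
        veg = veg_grid((4, 4))
        lue_dry = compute_lue(t, dry, ndvi, veg).as_array()
        lue_wet = compute_lue(t, wet, ndvi, veg).as_array()
        np.testing.assert_allclose(lue_dry, 0.5 * lue_wet)

    def test_missing_eps_max_raises(self):
        t = self._stack(np.full(12, 20.0))
        r = self._stack(np.full(12, 100.0))
        ndvi = self._stack(np.full(12, 0.6))
        with pytest.raises(ValueError, match="known codes"):
            compute_lue(t, r, ndvi, veg_grid((4, 4), code=9))


@pytest.fixture(scope="module")
def inputs():
    from vegcarbon.synthetic import SyntheticScenario

    sc = SyntheticScenario(shape=(10, 10), n_years=2, seed=3)
    climate = generate_climate(sc)
    ndvi, vegtype = generate_vegetation(sc, climate)
    return sc, climate, ndvi, vegtype


class TestNpp:

    def test_identity_npp_equals_apar_times_lue(self, inputs):
        _, climate, ndvi, vegtype = inputs
        cube = compute_npp(climate, ndvi, vegtype)
        for npp, apar, lue in zip(cube.npp_monthly.layers, cube.apar.layers,
                                  cube.lue.layers):
            valid = ~npp.nodata_mask
            np.testing.assert_array_equal(npp.values[valid],
                                          (apar.values * lue.values)[valid])

    def test_annual_is_sum_of_months(self, inputs):
        _, climate, ndvi, vegtype = inputs
        cube = compute_npp(climate, ndvi, vegtype)
        monthly = cube.npp_monthly.as_array()
        annual = cube.npp_annual.as_array()
        np.testing.assert_allclose(annual[0], monthly[:12].sum(axis=0))
        np.testing.assert_allclose(annual[1], monthly[12:].sum(axis=0))

    def test_npp_nonnegative(self, inputs):
        _, climate, ndvi, vegtype = inputs
        cube = compute_npp(climate, ndvi, vegtype)
        assert np.nanmin(cube.npp_monthly.as_array()) >= 0

    def test_doubling_sol_doubles_npp(self, inputs):
        _, climate, ndvi, vegtype = inputs
        cube1 = compute_npp(climate, ndvi, vegtype)
        doubled = MonthlyClimate(
            climate.temperature,
            climate.precipitation,
            GridStack([lyr.with_values(lyr.values * 2) for lyr in
                       climate.solar_radiation.layers],
                      time_index=climate.solar_radiation.time_index),
        )
        cube2 = compute_npp(doubled, ndvi, vegtype)
        np.testing.assert_allclose(cube2.npp_monthly.as_array(),
                                   2 * cube1.npp_monthly.as_array())

    def test_time_index_mismatch_rejected(self, inputs):
        _, climate, ndvi, vegtype = inputs
        shifted = GridStack(ndvi.layers, time_index=[(y + 1, m) for y, m in
                                                     ndvi.time_index])
        with pytest.raises(ValueError, match="time"):
            compute_npp(climate, shifted, vegtype)


class TestValidation:
    def test_identity_r_one(self):
        rng = np.random.default_rng(2)
        g = make_grid(rng.uniform(200, 900, (20, 20)))
        stats = validate_npp(g, g, n_points=100, seed=0)
        assert stats.r == pytest.approx(1.0)
        assert stats.r2 == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        g = make_grid(rng.uniform(200, 900, (20, 20)))
        ref = g.with_values(2 * g.values + 5)
        stats = validate_npp(g, ref, n_points=100, seed=0)
        assert stats.r == pytest.approx(1.0)

    def test_independent_reference_uncorrelated(self):
        rng = np.random.default_rng(7)
        hits = 0
        reps = 40
        for k in range(reps):
            a = make_grid(rng.normal(500, 100, (15, 15)))
            b = make_grid(rng.normal(500, 100, (15, 15)))
            stats = validate_npp(a, b, n_points=100, seed=k)
            hits += abs(stats.r) < 0.3
        assert hits / reps >= 0.95

    def test_too_few_valid_pixels_raises(self):
        g = make_grid(np.ones((5, 5)))
        with pytest.raises(ValueError, match="valid"):
            validate_npp(g, g, n_points=100, seed=0)
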