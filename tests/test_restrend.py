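"""Residual-trend attribution: selection, regression, decomposition, tables."""

import numpy as np
import pytest

from grasstrend import (
    ClimateSpec,
    GridStack,
    RegionSpec,
    SceneConfig,
    classify_driver,
    classify_scenario,
    decompose,
    fit_pixel_regressions,
    generate_scene,
    ols_slope_map,
    select_climate_variables,
)
from grasstrend.restrend import SCENARIO_LABELS, attribute, driver_code

# The full 36-row scenario table: (NDVI driver code, CV driver code) -> id.
SCENARIO_TABLE = {
    1: [("CDNI", "CDCD"), ("CDNI", "BDCD"), ("BDNI", "CDCD")],
    2: [("HDNI", "HDCD"), ("HDNI", "BDCD"), ("BDNI", "HDCD")],
    3: [("CDNI", "HDCD"), ("HDNI", "CDCD"), ("BDNI", "BDCD")],
    4: [("CDNI", "CDCI"), ("CDNI", "BDCI"), ("BDNI", "CDCI")],
    5: [("HDNI", "HDCI"), ("HDNI", "BDCI"), ("BDNI", "HDCI")],
    6: [("CDNI", "HDCI"), ("HDNI", "CDCI"), ("BDNI", "BDCI")],
    7: [("CDND", "CDCI"), ("CDND", "BDCI"), ("BDND", "CDCI")],
    8: [("HDND", "HDCI"), ("HDND", "BDCI"), ("BDND", "HDCI")],
    9: [("CDND", "HDCI"), ("HDND", "CDCI"), ("BDND", "BDCI")],
    10: [("CDND", "CDCD"), ("CDND", "BDCD"), ("BDND", "CDCD")],
    11: [("HDND", "HDCD"), ("HDND", "BDCD"), ("BDND", "HDCD")],
    12: [("CDND", "HDCD"), ("HDND", "CDCD"), ("BDND", "BDCD")],
}


def make_stack(values):
    values = np.asarray(values, dtype=float)
    return GridStack(values=values, years=np.arange(2000, 2000 + values.shape[0]))


class TestDriverTable:
    @pytest.mark.parametrize("obs, c, h, expected", [
        (+0.004, +0.005, -0.001, ("climate", 100.0, 0.0)),
        (+0.004, -0.001, +0.005, ("human", 0.0, 100.0)),
        (+0.004, +0.003, +0.001, ("both", 75.0, 25.0)),
        (-0.004, -0.005, +0.001, ("climate", 100.0, 0.0)),
        (-0.004, +0.001, -0.005, ("human", 0.0, 100.0)),
        (-0.004, -0.003, -0.001, ("both", 75.0, 25.0)),
    ])
    def test_six_rows(self, obs, c, h, expected):
        driver, cp, hp = classify_driver(obs, c, h)
        assert driver == expected[0]
        assert cp == pytest.approx(expected[1])
        assert hp == pytest.approx(expected[2])

    def test_zero_observed_slope_rejected(self):
        with pytest.raises(ValueError, match="Stable"):
            classify_driver(0.0, 0.001, -0.001)

    def test_zero_component_attributed_to_other(self):
        assert classify_driver(0.004, 0.004, 0.0)[0] == "climate"
        assert classify_driver(-0.004, 0.0, -0.004)[0] == "human"

    def test_impossible_pattern_rejected(self):
        with pytest.raises(ValueError, match="driver table"):
            classify_driver(0.004, -0.001, -0.001)

    def test_driver_codes(self):
        assert driver_code("climate", True, "ndvi") == "CDNI"
        assert driver_code("both", False, "cv") == "BDCD"


class TestScenarioTable:
    @pytest.mark.parametrize(
        "sid, pair",
        [(sid, pair) for sid, pairs in SCENARIO_TABLE.items() for pair in pairs],
    )
    def test_all_36_rows(self, sid, pair):
        got_id, got_label = classify_scenario(*pair)
        assert got_id == sid
        assert got_label == SCENARIO_LABELS[sid][0]

    def test_complete_partition(self):
        # every (NDVI code, CV code) combination maps to exactly one scenario
        ndvi_codes = [a + "DN" + d for a in "CHB" for d in "ID"]
        cv_codes = [a + "DC" + d for a in "CHB" for d in "ID"]
        seen = {}
        for n in ndvi_codes:
            for c in cv_codes:
                sid, _ = classify_scenario(n, c)
                seen.setdefault(sid, 0)
                seen[sid] += 1
        assert sorted(seen) == list(range(1, 13))
        assert all(v == 3 for v in seen.values())

    @pytest.mark.parametrize("pair", [("CDCI", "CDNI"), ("XDNI", "CDCD"), ("CDNI", "CD")])
    def test_malformed_pairs_rejected(self, pair):
        with pytest.raises(ValueError):
            classify_scenario(*pair)


class TestPixelRegression:
    def exact_scene(self, noise=0.0, n=12):
        rng = np.random.default_rng(8)
        ny = 20
        T = rng.standard_normal((ny, n, n)) + 2.0
        P = 50 * rng.standard_normal((ny, n, n)) + 400
        S = 100 * rng.standard_normal((ny, n, n)) + 2800
        ndvi = 0.01 * T + 0.0005 * P + 0.0001 * S + 0.1
        if noise:
            ndvi = ndvi + noise * rng.standard_normal(ndvi.shape)
        climate = {"T": make_stack(T), "P": make_stack(P), "S": make_stack(S)}
        return make_stack(ndvi), climate

    def test_noiseless_exact_recovery(self):
        ndvi, climate = self.exact_scene()
        regs = fit_pixel_regressions(ndvi, climate, ["T", "P", "S"])
        np.testing.assert_allclose(regs.coefficients[0], 0.01, atol=1e-9)
        np.testing.assert_allclose(regs.coefficients[1], 0.0005, atol=1e-9)
        np.testing.assert_allclose(regs.coefficients[2], 0.0001, atol=1e-9)
        np.testing.assert_allclose(regs.intercept, 0.1, atol=1e-7)
        np.testing.assert_allclose(regs.r_squared, 1.0, atol=1e-9)

    def test_constant_ndvi_degenerate_fit(self):
        ndvi, climate = self.exact_scene()
        const = make_stack(np.full_like(ndvi.values, 0.37))
        regs = fit_pixel_regressions(const, climate, ["T", "P", "S"])
        np.testing.assert_allclose(regs.coefficients, 0.0, atol=1e-10)
        np.testing.assert_allclose(regs.intercept, 0.37, atol=1e-10)

    def test_nodata_year_makes_pixel_nodata(self):
        ndvi, climate = self.exact_scene()
        ndvi.values[3, 0, 0] = np.nan
        regs = fit_pixel_regressions(ndvi, climate, ["T", "P", "S"])
        assert np.isnan(regs.coefficients[0, 0, 0])
        assert np.isfinite(regs.coefficients[0, 0, 1])

    def test_too_few_years_rejected(self):
        ndvi, climate = self.exact_scene()
        short = make_stack(ndvi.values[:4])
        short_climate = {k: make_stack(v.values[:4]) for k, v in climate.items()}
        with pytest.raises(ValueError, match="years"):
            fit_pixel_regressions(short, short_climate, ["T", "P", "S"])


class TestDecompose:
    def test_identical_obs_and_pred_give_zero_residuals(self, rng):
        v = rng.random((20, 8, 8)) + 0.3
        obs = make_stack(v)
        res = decompose(obs, make_stack(v.copy()))
        np.testing.assert_array_equal(res.ndvi_h.values, 0.0)
        valid = ~np.isnan(res.cv_h.values)
        np.testing.assert_allclose(res.cv_h.values[valid], 0.0, atol=1e-14)

    def test_conservation_bit_exact(self, rng):
        obs = make_stack(rng.random((15, 6, 6)))
        pred = make_stack(rng.random((15, 6, 6)))
        res = decompose(obs, pred)
        np.testing.assert_array_equal(res.ndvi_h.values + pred.values, obs.values)

    def test_additive_trend_appears_in_residual(self, rng):
        base = rng.random((20, 6, 6)) + 0.3
        beta = -0.004
        trend = beta * np.arange(20)[:, None, None]
        res = decompose(make_stack(base + trend), make_stack(base))
        np.testing.assert_allclose(ols_slope_map(res.ndvi_h), beta, atol=1e-12)

    def test_slope_additivity(self, rng):
        obs = make_stack(rng.random((20, 6, 6)))
        pred = make_stack(rng.random((20, 6, 6)))
        res = decompose(obs, pred)
        np.testing.assert_allclose(
            ols_slope_map(res.ndvi_obs),
            ols_slope_map(res.ndvi_c) + ols_slope_map(res.ndvi_h),
            atol=1e-12,
        )


class TestSelection:
    def test_single_dominant_predictor(self):
        cfg = SceneConfig(
            n_rows=12, n_cols=12,
            climate={
                "temperature": ClimateSpec(mean=0.0, trend=0.02, noise_sd=0.5,
                                           pixel_noise_sd=0.2),
                "wind": ClimateSpec(mean=2.0, noise_sd=0.3, pixel_noise_sd=0.1),
                "radiation": ClimateSpec(mean=6000.0, noise_sd=100.0, pixel_noise_sd=40.0),
            },
            regions=[RegionSpec((0, 12), (0, 12), coeffs={"temperature": 0.1})],
            ndvi_noise_sd=0.005, seed=6,
        )
        ndvi, climate, _ = generate_scene(cfg)
        report = select_climate_variables(ndvi, climate, seed=1, n_trees=200,
                                          max_rows=2000, n_repeats=3)
        assert report.selected[0] == "temperature"
        assert report.rf_importance.index[0] == "temperature"
        # dominant predictor holds nearly all the importance mass
        share = report.rf_importance.clip(lower=0)
        assert share["temperature"] / share.sum() > 0.9

    def test_constant_candidate_excluded_with_warning(self, small_scene):
        _, ndvi, climate, _ = small_scene
        climate = dict(climate)
        constant = climate["wind"].copy(values=np.full_like(climate["wind"].values, 2.0))
        climate["wind"] = constant
        with pytest.warns(UserWarning, match="constant"):
            report = select_climate_variables(ndvi, climate, seed=0, n_trees=50,
                                              max_rows=1000, n_repeats=2)
        assert "wind" not in report.rf_importance.index

    def test_pure_noise_ndvi_rarely_selects(self):
        # no climate response at all: the selected set is usually empty
        empty = 0
        runs = 12
        for s in range(runs):
            cfg = SceneConfig(
                n_rows=10, n_cols=10,
                regions=[RegionSpec((0, 10), (0, 10), coeffs={})],
                ndvi_noise_sd=0.05, ndvi_texture_sd=0.0, seed=100 + s,
            )
            ndvi, climate, _ = generate_scene(cfg)
            report = select_climate_variables(ndvi, climate, seed=s, n_trees=100,
                                              max_rows=1500, n_repeats=2)
            empty += not report.selected
        assert empty / runs >= 0.6


class TestEndToEndAttribution:
    def test_contributions_sum_to_100(self, small_scene):
        _, ndvi, climate, _ = small_scene
        regs = fit_pixel_regressions(ndvi, climate, ["temperature", "precipitation"])
        res = decompose(ndvi, regs.predicted)
        drivers, _ = attribute(res, slope_mode="ols")
        for cp, hp in [(drivers.ndvi_climate_pct, drivers.ndvi_human_pct),
                       (drivers.cv_climate_pct, drivers.cv_human_pct)]:
            defined = ~np.isnan(cp)
            assert defined.any()
            np.testing.assert_allclose(cp[defined] + hp[defined], 100.0, atol=1e-6)

    def test_sen_mode_also_conserves(self, small_scene):
        _, ndvi, climate, _ = small_scene
        regs = fit_pixel_regressions(ndvi, climate, ["temperature", "precipitation"])
        res = decompose(ndvi, regs.predicted)
        drivers, _ = attribute(res, slope_mode="sen")
        defined = ~np.isnan(drivers.ndvi_climate_pct)
        np.testing.assert_allclose(
            drivers.ndvi_climate_pct[defined] + drivers.ndvi_human_pct[defined],
            100.0, atol=1e-6)
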