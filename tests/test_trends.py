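"""Sen slope, Mann-Kendall, windowed statistics, trend and correlation maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grasstrend import (
    GridStack,
    correlation_map,
    mann_kendall,
    sen_slope,
    trend_map,
    window_cv,
    window_median,
)

series_strategy = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=5, max_size=25
).filter(lambda x: len(set(x)) > 1)


def make_stack(values):
    values = np.asarray(values, dtype=float)
    return GridStack(values=values, years=np.arange(2000, 2000 + values.shape[0]))


class TestSenSlope:
    @pytest.mark.parametrize("series, years, expected", [
        ([5, 5, 5, 5], None, 0.0),
        ([2, 4, 6, 8, 10], None, 2.0),
        ([1, 3, 2, 5], [1, 2, 3, 4], 7 / 6),  # pairwise slopes {2,.5,4/3,-1,1,3}
    ])
    def test_frozen_examples(self, series, years, expected):
        assert sen_slope(series, years) == pytest.approx(expected, abs=1e-12)

    def test_too_few_points(self):
        assert np.isnan(sen_slope([1.0]))
        assert np.isnan(sen_slope([1.0, np.nan]))

    def test_nan_dropped(self):
        assert sen_slope([1, np.nan, 3]) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(series_strategy, st.floats(-5, 5, allow_nan=False), st.floats(-10, 10))
    def test_affine_equivariance(self, xs, k, c):
        x = np.array(xs)
        got = sen_slope(k * x + c)
        np.testing.assert_allclose(got, k * sen_slope(x), atol=1e-7, rtol=1e-7)


class TestMannKendall:
    def test_strictly_increasing_s_is_max(self):
        s, z, p = mann_kendall([1, 2, 3, 4, 5])
        assert s == 10 and z > 0 and p < 0.05

    def test_constant_series(self):
        s, z, p = mann_kendall([3.0, 3.0, 3.0, 3.0])
        assert s == 0 and z == 0.0 and p == 1.0

    def test_frozen_example(self):
        s, z, p = mann_kendall([1, 3, 2, 5])
        assert s == 4  # sign terms 1+1+1-1+1+1
        # Var(S) = 4*3*13/18 with no ties; Z = (S-1)/sqrt(Var)
        assert z == pytest.approx(3 / np.sqrt(4 * 3 * 13 / 18))

    def test_too_short(self):
        s, z, p = mann_kendall([1, 2, 3])
        assert np.isnan(z)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(-500, 500), min_size=5, max_size=25))
    def test_s_invariant_under_monotone_transform(self, xs):
        x = np.array(xs, dtype=float)
        s1, _, _ = mann_kendall(x)
        s2, _, _ = mann_kendall(np.exp(x / 100.0))
        assert s1 == s2

    @settings(max_examples=50, deadline=None)
    @given(series_strategy)
    def test_antisymmetry_under_time_reversal(self, xs):
        x = np.array(xs)
        assert mann_kendall(x)[0] == -mann_kendall(x[::-1])[0]

    def test_tie_correction_reduces_variance(self):
        # heavy ties shrink Var(S), hence larger |Z| for the same S
        _, z_ties, _ = mann_kendall([1, 1, 1, 2, 2, 3])
        s, _, _ = mann_kendall([1, 1, 1, 2, 2, 3])
        var_no_ties = 6 * 5 * 17 / 18
        z_without = (s - 1) / np.sqrt(var_no_ties)
        assert abs(z_ties) > abs(z_without)


class TestWindows:
    def test_cv_frozen_example(self):
        band = np.arange(1.0, 10.0).reshape(3, 3)
        got = window_cv(band)
        assert got[1, 1] == pytest.approx(np.sqrt(7.5) / 5)  # sd sqrt(60/8), mean 5
        assert np.isnan(got[0, 0])  # edges incomplete

    def test_cv_uniform_window_is_zero(self):
        assert window_cv(np.full((3, 3), 4.2))[1, 1] == 0.0

    def test_cv_scale_invariance(self, rng):
        band = rng.random((6, 6)) + 0.5
        np.testing.assert_allclose(window_cv(3.7 * band), window_cv(band), atol=1e-12)

    def test_cv_nonpositive_mean_is_nodata(self):
        assert np.isnan(window_cv(np.full((3, 3), -1.0))[1, 1])

    def test_cv_nodata_propagates(self):
        band = np.ones((5, 5))
        band[2, 2] = np.nan
        got = window_cv(band)
        assert np.isnan(got[1:4, 1:4]).all()      # all windows touching the hole

    def test_median_examples(self, rng):
        band = np.arange(1.0, 10.0).reshape(3, 3)
        assert window_median(band)[1, 1] == 5.0
        assert window_median(np.full((3, 3), 2.5))[1, 1] == 2.5
        shuffled = band.copy().ravel()
        rng.shuffle(shuffled)
        assert window_median(shuffled.reshape(3, 3))[1, 1] == 5.0


class TestTrendMap:
    def test_noiseless_linear_stack(self):
        t = np.arange(20)
        stack = make_stack(0.3 + 0.005 * t[:, None, None] * np.ones((1, 4, 4)))
        tm = trend_map(stack, alpha=0.05)
        np.testing.assert_allclose(tm.slope, 0.005, atol=1e-12)
        assert tm.significant.all()

    def test_time_reversal_negates(self, rng):
        v = rng.standard_normal((10, 5, 5))
        tm_f = trend_map(make_stack(v))
        tm_b = trend_map(make_stack(v[::-1]))
        np.testing.assert_allclose(tm_f.slope, -tm_b.slope, atol=1e-10)
        np.testing.assert_array_equal(tm_f.s_statistic, -tm_b.s_statistic)

    def test_gappy_pixels_use_valid_years_only(self, rng):
        v = rng.standard_normal((10, 3, 3))
        v[::2, 0, 0] = np.nan            # 5 valid years at (0, 0)
        v[:8, 0, 1] = np.nan             # only 2 valid -> nodata
        tm = trend_map(make_stack(v))
        assert np.isfinite(tm.slope[0, 0])
        assert np.isnan(tm.slope[0, 1])

    def test_sign_consistency_invariant(self, rng):
        v = rng.standard_normal((12, 6, 6))
        tm = trend_map(make_stack(v))
        s, z = tm.s_statistic, tm.z
        assert np.all(np.sign(z[s != 0]) == np.sign(s[s != 0]))
        assert np.all(z[s == 0] == 0)

    def test_type_one_error_calibrated(self, rng):
        # pure-noise stack: significant fraction ~ alpha
        v = rng.standard_normal((20, 50, 50))
        tm = trend_map(make_stack(v), alpha=0.05)
        frac = tm.significant.mean()
        tol = 2 * np.sqrt(0.05 * 0.95 / 2500)
        assert abs(frac - 0.05) < tol + 0.01


class TestCorrelationMap:
    def test_perfect_linear_relationship(self, rng):
        p = rng.random((15, 4, 4))
        ndvi = make_stack(2 * p + 1)
        np.testing.assert_allclose(correlation_map(ndvi, make_stack(p)), 1.0)

    def test_independent_noise_near_zero(self, rng):
        a = make_stack(rng.standard_normal((20, 30, 30)))
        b = make_stack(rng.standard_normal((20, 30, 30)))
        r = correlation_map(a, b)
        assert abs(np.nanmean(r)) < 3 / np.sqrt(20 * 900)

    def test_constant_series_nodata(self):
        a = make_stack(np.random.default_rng(0).random((8, 2, 2)))
        b = make_stack(np.ones((8, 2, 2)))
        assert np.isnan(correlation_map(a, b)).all()

    def test_year_mismatch_rejected(self, rng):
        a = make_stack(rng.random((8, 2, 2)))
        b = make_stack(rng.random((9, 2, 2)))
        with pytest.raises(ValueError, match="years"):
            correlation_map(a, b)
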