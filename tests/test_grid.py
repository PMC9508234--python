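"""Raster stack data model, I/O round-trips, masking and resampling."""

import numpy as np
import pytest

from grasstrend import (
    AlignmentError,
    GridStack,
    GridTransform,
    Mask,
    apply_mask,
    read_mask,
    read_stack,
    resample_to,
    write_mask,
    write_stack,
)


def make_stack(values, transform=None, years=None, crs="local"):
    values = np.asarray(values, dtype=float)
    years = np.arange(2000, 2000 + values.shape[0]) if years is None else years
    return GridStack(values=values, years=years,
                     transform=transform or GridTransform(), crs_id=crs)


class TestGridStack:
    def test_years_must_match_bands(self):
        with pytest.raises(ValueError, match="years"):
            GridStack(values=np.zeros((3, 2, 2)), years=[2000, 2001])

    def test_years_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            GridStack(values=np.zeros((2, 2, 2)), years=[2001, 2000])

    def test_nodata_mask_any_year(self):
        v = np.zeros((2, 2, 2))
        v[1, 0, 1] = np.nan
        s = make_stack(v)
        assert s.nodata_mask[0, 1] and not s.nodata_mask[0, 0]


class TestIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        v = rng.standard_normal((5, 8, 9))
        v[:, 2, 3] = np.nan
        s = make_stack(v, GridTransform(500000.0, 4.2e6, 30.0, 30.0), crs="EPSG:32647")
        s.variable, s.units = "ndvi", ""
        p = write_stack(s, tmp_path / "stack.tif")
        back = read_stack(p)
        np.testing.assert_array_equal(back.values, s.values)
        np.testing.assert_array_equal(back.years, s.years)
        assert back.transform.close_to(s.transform)
        assert back.crs_id == s.crs_id and back.variable == "ndvi"

    def test_multiple_single_band_files(self, tmp_path, rng):
        paths = []
        for i in range(3):
            s = make_stack(rng.standard_normal((1, 4, 4)), years=[2000 + i])
            paths.append(write_stack(s, tmp_path / f"y{i}.tif"))
        stack = read_stack(paths, years=[2000, 2001, 2002])
        assert stack.n_years == 3

    def test_band_count_mismatch(self, tmp_path, rng):
        p = write_stack(make_stack(rng.standard_normal((3, 4, 4))), tmp_path / "a.tif")
        with pytest.raises(ValueError, match="years"):
            read_stack(p, years=[2000, 2001])

    def test_differing_pixel_size_is_alignment_error(self, tmp_path, rng):
        a = make_stack(rng.standard_normal((1, 4, 4)), GridTransform(0, 4, 1, 1))
        b = make_stack(rng.standard_normal((1, 4, 4)), GridTransform(0, 4, 2, 2))
        pa = write_stack(a, tmp_path / "a.tif")
        pb = write_stack(b, tmp_path / "b.tif")
        with pytest.raises(AlignmentError):
            read_stack([pa, pb], years=[2000, 2001])

    def test_mask_round_trip(self, tmp_path, rng):
        m = Mask(values=rng.random((6, 6)) > 0.5, provenance="road_river")
        p = write_mask(m, tmp_path / "mask.tif")
        back = read_mask(p)
        np.testing.assert_array_equal(back.values, m.values)
        assert back.provenance == "road_river"


class TestResample:
    def test_identity_on_same_grid(self, rng):
        s = make_stack(rng.standard_normal((2, 5, 5)))
        out = resample_to(s, s, "bilinear")
        np.testing.assert_array_equal(out.values, s.values)

    def test_constant_preserved_downscaling(self):
        coarse = make_stack(np.full((1, 4, 4), 7.5),
                            GridTransform(0, 4000, 1000, 1000))
        fine = make_stack(np.zeros((1, 100, 100)), GridTransform(500, 3500, 30, 30))
        out = resample_to(coarse, fine, "bilinear")
        valid = ~np.isnan(out.values)
        assert valid.any()
        np.testing.assert_allclose(out.values[valid], 7.5)

    def test_bilinear_midpoint_symmetry(self):
        src = make_stack(np.array([[[0.0, 2.0], [2.0, 4.0]]]), GridTransform(0, 2, 1, 1))
        tgt = make_stack(np.zeros((1, 1, 1)), GridTransform(0.5, 1.5, 1, 1))
        out = resample_to(src, tgt, "bilinear")
        np.testing.assert_allclose(out.values[0, 0, 0], 2.0)

    def test_bilinear_stays_in_envelope(self, rng):
        src = make_stack(rng.random((1, 10, 10)), GridTransform(0, 10, 1, 1))
        tgt = make_stack(np.zeros((1, 30, 30)), GridTransform(0, 10, 1 / 3, 1 / 3))
        out = resample_to(src, tgt, "bilinear")
        v = out.values[~np.isnan(out.values)]
        assert v.min() >= src.values.min() - 1e-12
        assert v.max() <= src.values.max() + 1e-12

    def test_nearest_category_closure(self, rng):
        cats = rng.integers(0, 4, size=(1, 8, 8)).astype(float)
        src = make_stack(cats, GridTransform(0, 8, 1, 1))
        tgt = make_stack(np.zeros((1, 20, 20)), GridTransform(0, 8, 0.4, 0.4))
        out = resample_to(src, tgt, "nearest")
        got = set(np.unique(out.values[~np.isnan(out.values)]))
        assert got <= set(np.unique(cats))

    def test_nodata_not_interpolated(self):
        v = np.ones((1, 4, 4))
        v[0, 1, 1] = np.nan
        src = make_stack(v, GridTransform(0, 4, 1, 1))
        tgt = make_stack(np.zeros((1, 8, 8)), GridTransform(0, 4, 0.5, 0.5))
        out = resample_to(src, tgt, "bilinear")
        # every valid output cell must be exactly 1 (no blended nodata)
        valid = out.values[~np.isnan(out.values)]
        np.testing.assert_allclose(valid, 1.0)

    def test_disjoint_extents(self):
        a = make_stack(np.zeros((1, 4, 4)), GridTransform(0, 4, 1, 1))
        b = make_stack(np.zeros((1, 4, 4)), GridTransform(100, 4, 1, 1))
        with pytest.raises(AlignmentError, match="disjoint"):
            resample_to(a, b)


class TestApplyMask:
    def test_all_include_is_identity(self, rng):
        s = make_stack(rng.standard_normal((3, 6, 6)))
        out = apply_mask(s, Mask(np.ones((6, 6), bool)), buffer_pixels=0)
        np.testing.assert_array_equal(out.values, s.values)

    def test_single_exclusion_dilates_to_block(self):
        s = make_stack(np.ones((1, 7, 7)))
        m = np.ones((7, 7), bool)
        m[3, 3] = False
        out = apply_mask(s, Mask(m), buffer_pixels=1)
        assert np.isnan(out.values[0, 2:5, 2:5]).all()
        assert np.isfinite(out.values[0]).sum() == 49 - 9

    def test_wrong_shape_rejected(self):
        s = make_stack(np.ones((1, 5, 5)))
        with pytest.raises(ValueError, match="shape"):
            apply_mask(s, Mask(np.ones((4, 4), bool)))

    def test_idempotent(self, rng):
        s = make_stack(rng.standard_normal((2, 9, 9)))
        m = Mask(rng.random((9, 9)) > 0.3)
        once = apply_mask(s, m, buffer_pixels=1)
        twice = apply_mask(once, m, buffer_pixels=1)
        np.testing.assert_array_equal(once.values, twice.values)
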