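"""Raster containers, NetCDF/TIFF round-trips, resampling, compositing."""

import numpy as np
import pandas as pd
import pytest

from rastertrend.raster import (
    AnnualSeries,
    RasterStack,
    WetlandMask,
    growing_season_annual,
    mvc_monthly,
    read_mask,
    read_stack,
    resample_nearest,
    unchanged_mask,
    write_mask,
    write_stack,
)
from rastertrend.synthetic import gen_daily_month

from conftest import make_stack


class TestContainers:
    def test_annual_series_validation(self):
        with pytest.raises(ValueError):
            AnnualSeries([1982, 1982, 1983], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            AnnualSeries([1982, 1983], [1.0, 2.0, 3.0])

    def test_stack_requires_monotone_time(self):
        with pytest.raises(ValueError):
            RasterStack(
                np.zeros((2, 2, 2)),
                pd.DatetimeIndex(["2001-01-01", "2000-01-01"]),
                [0.0, 1.0], [0.0, 1.0],
            )

    def test_mask_rejects_non_binary(self):
        with pytest.raises(ValueError):
            WetlandMask(np.array([[0.5]]), [0.0], [0.0])

    def test_subset_years(self, random_annual_stack):
        sub = random_annual_stack.subset_years(1984, 1986)
        assert sub.shape[0] == 3
        assert list(sub.years) == [1984, 1985, 1986]


class TestIO:
    def test_netcdf_round_trip_bit_exact(self, tmp_path, random_annual_stack):
        stack = random_annual_stack
        stack.values[2, 1, 1] = np.nan
        path = tmp_path / "stack.nc"
        write_stack(stack, path)
        back = read_stack(path, "NDVI")
        np.testing.assert_array_equal(back.values, stack.values)
        np.testing.assert_array_equal(back.lat, stack.lat)
        np.testing.assert_array_equal(back.lon, stack.lon)
        assert list(back.time) == list(stack.time)

    def test_missing_variable_names_available(self, tmp_path,
                                              random_annual_stack):
        path = tmp_path / "stack.nc"
        write_stack(random_annual_stack, path)
        with pytest.raises(KeyError, match="NDVI"):
            read_stack(path, "TMP")

    def test_mask_round_trip_and_reference_check(self, tmp_path,
                                                 random_annual_stack):
        stack = random_annual_stack
        rng = np.random.default_rng(1)
        mask = WetlandMask(rng.random(stack.shape[1:]) > 0.5, stack.lat,
                           stack.lon, epoch="1980")
        path = tmp_path / "mask.tif"
        write_mask(mask, path)
        back = read_mask(path, reference=stack)
        np.testing.assert_array_equal(back.values, mask.values)
        assert back.epoch == "1980"
        small = make_stack(np.zeros((3, 2, 2)))
        with pytest.raises(ValueError, match="shape"):
            read_mask(path, reference=small)


class TestResample:
    def test_identity_on_same_grid(self, random_annual_stack):
        stack = random_annual_stack
        out = resample_nearest(stack, stack.lat, stack.lon)
        np.testing.assert_array_equal(out.values, stack.values)

    def test_constant_field_upsampled_stays_constant(self):
        stack = make_stack(np.full((2, 4, 4), 0.7),
                           lat=np.arange(40.0, 42.0, 0.5),
                           lon=np.arange(110.0, 112.0, 0.5))
        out = resample_nearest(stack, np.arange(40.0, 42.0, 0.05),
                               np.arange(110.0, 112.0, 0.05))
        np.testing.assert_allclose(out.values, 0.7)

    def test_block_replication_matches_nearest_center_oracle(self):
        src_lat, src_lon = np.array([0.0, 1.0]), np.array([0.0, 1.0])
        vals = np.arange(4.0).reshape(1, 2, 2)
        stack = make_stack(vals, lat=src_lat, lon=src_lon)
        tgt_lat = np.array([-0.2, 0.2, 0.8, 1.2])
        tgt_lon = np.array([-0.1, 0.4, 0.6, 1.1])
        out = resample_nearest(stack, tgt_lat, tgt_lon)
        expected = np.empty((4, 4))
        for a, la in enumerate(tgt_lat):
            for b, lo in enumerate(tgt_lon):
                i = int(np.argmin(np.abs(src_lat - la)))
                j = int(np.argmin(np.abs(src_lon - lo)))
                expected[a, b] = vals[0, i, j]
        np.testing.assert_array_equal(out.values[0], expected)

    def test_idempotent_on_own_output_grid(self, random_annual_stack):
        stack = random_annual_stack
        coarse = resample_nearest(stack, stack.lat[::2], stack.lon[::2])
        again = resample_nearest(coarse, coarse.lat, coarse.lon)
        np.testing.assert_array_equal(coarse.values, again.values)

    def test_disjoint_extents_raise(self, random_annual_stack):
        with pytest.raises(ValueError, match="disjoint"):
            resample_nearest(random_annual_stack, np.array([80.0, 81.0]),
                             np.array([0.0, 1.0]))


class TestUnchangedMask:
    def _mask(self, values):
        values = np.asarray(values, dtype=bool)
        ny, nx = values.shape
        return WetlandMask(values, np.arange(float(ny)), np.arange(float(nx)))

    def test_idempotence(self):
        m = self._mask([[1, 0], [1, 1]])
        out = unchanged_mask(m, m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_disjoint_gives_all_zero(self):
        a = self._mask([[1, 0], [0, 0]])
        b = self._mask([[0, 0], [0, 1]])
        assert unchanged_mask(a, b).n_pixels == 0

    def test_random_masks_match_cellwise_oracle(self, rng):
        for _ in range(20):
            a = self._mask(rng.random((6, 7)) > 0.5)
            b = self._mask(rng.random((6, 7)) > 0.5)
            out = unchanged_mask(a, b)
            for i in range(6):
                for j in range(7):
                    assert out.values[i, j] == (
                        a.values[i, j] and b.values[i, j]
                    )
            assert out.n_pixels <= min(a.n_pixels, b.n_pixels)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            unchanged_mask(self._mask([[1]]), self._mask([[1, 0]]))


class TestMVC:
    def _daily_stack(self, values):
        """values: (n_days, ny, nx) mapped onto consecutive days."""
        return make_stack(values, freq="D", start_year=2000)

    def test_constant_month(self):
        out = mvc_monthly(self._daily_stack(np.full((28, 2, 2), 0.4)))
        np.testing.assert_allclose(out.values, 0.4)
        assert out.shape[0] == 1

    def test_picks_maximum(self):
        vals = np.array([0.1, 0.7, 0.3])[:, None, None] * np.ones((1, 1))
        out = mvc_monthly(self._daily_stack(vals))
        assert out.values[0, 0, 0] == pytest.approx(0.7)

    def test_random_cube_matches_loop_oracle(self, rng):
        vals = rng.uniform(0, 1, size=(70, 3, 3))  # spans >2 months
        drop = rng.random(vals.shape) < 0.2
        vals[drop] = np.nan
        daily = self._daily_stack(vals)
        out = mvc_monthly(daily)
        periods = daily.time.to_period("M")
        for k, p in enumerate(periods.unique().sort_values()):
            sel = np.asarray(periods == p)
            for i in range(3):
                for j in range(3):
                    col = vals[sel, i, j]
                    col = col[np.isfinite(col)]
                    if col.size:
                        assert out.values[k, i, j] == pytest.approx(col.max())
                        # the max is attained by some day
                        assert np.any(np.isclose(col, out.values[k, i, j]))
                    else:
                        assert np.isnan(out.values[k, i, j])

    def test_all_missing_month_stays_missing_with_warning(self):
        vals = np.full((28, 1, 1), np.nan)
        with pytest.warns(UserWarning, match="no valid observations"):
            out = mvc_monthly(self._daily_stack(vals))
        assert np.isnan(out.values).all()

    def test_composes_with_daily_dropout_generator(self):
        base = np.linspace(0.2, 0.8, 30)
        daily = gen_daily_month(base, dropout=0.3, seed=2)
        stack = self._daily_stack(daily[:, None, None] * np.ones((1, 1)))
        out = mvc_monthly(stack)
        assert out.values[0, 0, 0] == pytest.approx(np.nanmax(daily))


class TestGrowingSeason:
    def _monthly_stack(self, n_years, ny=2, nx=2, fill=0.6):
        n = n_years * 12
        vals = np.full((n, ny, nx), fill)
        return make_stack(vals, freq="MS", start_year=2000)

    def test_constant_mean(self):
        out = growing_season_annual(self._monthly_stack(2), reducer="mean")
        np.testing.assert_allclose(out.values, 0.6)
        assert out.shape[0] == 2

    def test_precipitation_sum(self):
        vals = np.zeros((12, 1, 1))
        vals[4:9, 0, 0] = [10, 20, 30, 20, 20]  # May..September
        stack = make_stack(vals, freq="MS", start_year=2000)
        out = growing_season_annual(stack, reducer="sum")
        assert out.values[0, 0, 0] == pytest.approx(100.0)

    def test_random_stack_matches_loop_oracle(self, rng):
        vals = rng.uniform(0, 1, size=(36, 3, 3))
        stack = make_stack(vals, freq="MS", start_year=2000)
        out = growing_season_annual(stack, reducer="mean")
        for k, year in enumerate([2000, 2001, 2002]):
            sel = (stack.time.year == year) & stack.time.month.isin(range(5, 10))
            np.testing.assert_allclose(out.values[k],
                                       vals[np.asarray(sel)].mean(axis=0),
                                       atol=1e-12)

    def test_strict_vs_lenient_missing_policy(self):
        vals = np.full((12, 1, 1), 0.5)
        vals[5, 0, 0] = np.nan  # June missing
        stack = make_stack(vals, freq="MS", start_year=2000)
        lenient = growing_season_annual(stack, policy="lenient")
        strict = growing_season_annual(stack, policy="strict")
        assert lenient.values[0, 0, 0] == pytest.approx(0.5)
        assert np.isnan(strict.values[0, 0, 0])

    def test_invalid_months_raise(self):
        with pytest.raises(ValueError):
            growing_season_annual(self._monthly_stack(1), months=[0, 5])
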