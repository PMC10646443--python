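"""Pearson/lagged/partial correlation and pixel-wise correlation fields."""

import numpy as np
import pytest

from rastertrend.association import (
    CorrelationCategory,
    categorize,
    correlation_field,
    lagged_pearson,
    partial_corr,
    partial_corr_series,
    pearson,
    regional_series,
)
from rastertrend.raster import AnnualSeries, WetlandMask
from rastertrend.synthetic import SceneSpec, gen_scene

from conftest import make_stack, series_from


class TestPearson:
    def test_identity(self, rng):
        x = rng.normal(size=10)
        assert pearson(x, x).r == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=10)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_hand_example(self):
        res = pearson(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
        assert res.r == pytest.approx(0.8)

    def test_symmetric_and_matches_scipy(self, rng):
        from scipy.stats import pearsonr

        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson(x, y)
        assert res.r == pytest.approx(pearson(y, x).r, abs=1e-14)
        ref = pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        base = pearson(x, y).r
        assert pearson(2 * x + 1, 3 * y - 2).r == pytest.approx(base, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson(np.ones(5), np.arange(5.0))

    def test_aligns_on_years(self):
        x = series_from([1.0, 2.0, 3.0], start_year=1982)
        y = series_from([5.0, 2.0, 4.0, 6.0], start_year=1981)
        res = pearson(x, y)  # overlap 1982-1984 -> y = [2, 4, 6]
        assert res.n_eff == 3
        assert res.r == pytest.approx(1.0)


class TestCategories:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (0.5, 0.01, CorrelationCategory.SIG_POSITIVE),
            (0.5, 0.30, CorrelationCategory.NONSIG_POSITIVE),
            (-0.5, 0.01, CorrelationCategory.SIG_NEGATIVE),
            (-0.5, 0.30, CorrelationCategory.NONSIG_NEGATIVE),
            (0.5, 0.05, CorrelationCategory.NONSIG_POSITIVE),  # boundary
            (0.0, 0.9, CorrelationCategory.NONSIG_POSITIVE),
        ],
    )
    def test_four_way(self, r, p, expected):
        assert categorize(r, p, alpha=0.05) is expected


class TestLagged:
    def test_lag_zero_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert lagged_pearson(x, y, 0).r == pytest.approx(pearson(x, y).r)

    def test_shifted_copy_perfect_at_lag_one(self):
        base = np.random.default_rng(7).normal(size=20)
        x = series_from(base[:-1], start_year=1983)      # x_t = base_{t-1}
        y = series_from(base, start_year=1982)
        res = lagged_pearson(x, y, 1)
        assert res.r == pytest.approx(1.0)
        assert res.n_eff == 19
        assert res.lag == 1

    def test_built_in_lag_detected_on_average(self):
        rng = np.random.default_rng(11)
        stronger = 0
        n_rep = 50
        for _ in range(n_rep):
            drv = rng.normal(size=40)
            y = series_from(drv, start_year=1982)  # driver (e.g. rainfall)
            # response follows the driver with a one-year delay plus noise
            x = series_from(drv[:-1] + 0.5 * rng.normal(size=39),
                            start_year=1983)
            r0 = abs(lagged_pearson(x, y, 0).r)
            r1 = abs(lagged_pearson(x, y, 1).r)
            if r1 > r0:
                stronger += 1
        assert stronger / n_rep > 0.8

    def test_invalid_lag_raises(self, rng):
        with pytest.raises(ValueError):
            lagged_pearson(rng.normal(size=10), rng.normal(size=10), 3)


class TestPartialCorr:
    def test_no_confounding(self):
        assert partial_corr(0.6, 0.0, 0.0).r_xy_z == pytest.approx(0.6)

    def test_full_mediation(self):
        assert partial_corr(0.6 * 0.5, 0.6, 0.5).r_xy_z == pytest.approx(0.0)

    def test_degenerate_conditioning_raises(self):
        with pytest.raises(ValueError):
            partial_corr(0.5, 1.0, 0.3)

    def test_bounded_for_random_valid_inputs(self, rng):
        for _ in range(200):
            # correlations from a random valid 3x3 correlation matrix
            a = rng.normal(size=(3, 6))
            c = np.corrcoef(a)
            res = partial_corr(c[0, 1], c[0, 2], c[1, 2])
            assert -1.0 <= res.r_xy_z <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_residual_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=60)
        x = 0.5 * z + rng.normal(size=60)
        y = -0.7 * z + 0.3 * x + rng.normal(size=60)
        res = partial_corr_series(x, y, z)
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.r_xy_z == pytest.approx(oracle, abs=1e-10)

    def test_p_value_df(self):
        # zero partial correlation (full mediation) -> t = 0 -> p = 1
        res = partial_corr(0.3 * 0.2, 0.3, 0.2, n=40)
        assert res.r_xy_z == pytest.approx(0.0, abs=1e-15)
        assert res.p == pytest.approx(1.0)
        # and a strong residual association is significant
        assert partial_corr(0.9, 0.3, 0.2, n=40).p < 1e-6


class TestFieldAndRegion:
    def test_self_correlation_is_one_everywhere(self, random_annual_stack,
                                                full_mask):
        stack = random_annual_stack
        fld = correlation_field(stack, stack, full_mask(stack))
        np.testing.assert_allclose(fld.r[np.isfinite(fld.r)], 1.0)
        assert sum(fld.fractions.values()) == pytest.approx(1.0)

    def test_coupled_scene_mean_r_near_target(self):
        scene = gen_scene(SceneSpec(n_lat=10, n_lon=10, n_years=39,
                                    coupling={"TMP": 0.7}, mask_fraction=1.0,
                                    seed=9))
        fld = correlation_field(scene.ndvi, scene.climate["TMP"],
                                scene.mask_epoch1)
        assert np.nanmean(fld.r) == pytest.approx(0.7, abs=0.05)

    def test_map_equals_series_level_loop(self, rng, full_mask):
        nd = make_stack(rng.uniform(0, 1, size=(10, 3, 3)))
        cl = make_stack(rng.normal(size=(10, 3, 3)), variable="TMP")
        fld = correlation_field(nd, cl, full_mask(nd))
        for i in range(3):
            for j in range(3):
                ref = pearson(nd.values[:, i, j], cl.values[:, i, j])
                assert fld.r[i, j] == pytest.approx(ref.r, abs=1e-12)
                assert fld.p[i, j] == pytest.approx(ref.p, abs=1e-12)

    def test_regional_series_single_pixel(self, random_annual_stack):
        stack = random_annual_stack
        m = np.zeros(stack.shape[1:], bool)
        m[2, 3] = True
        mask = WetlandMask(m, stack.lat, stack.lon)
        out = regional_series(stack, mask)
        np.testing.assert_allclose(out.values, stack.values[:, 2, 3])

    def test_regional_series_matches_loop_mean(self, random_annual_stack,
                                               rng):
        stack = random_annual_stack
        stack.values[1, 0, 0] = np.nan
        m = rng.random(stack.shape[1:]) > 0.4
        m[0, 0] = True
        mask = WetlandMask(m, stack.lat, stack.lon)
        out = regional_series(stack, mask)
        for k in range(stack.shape[0]):
            vals = [stack.values[k, i, j]
                    for i, j in zip(*np.nonzero(m))
                    if np.isfinite(stack.values[k, i, j])]
            assert out.values[k] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_grid_mismatch_raises(self, random_annual_stack):
        other = make_stack(np.zeros((10, 2, 2)))
        with pytest.raises(ValueError):
            correlation_field(random_annual_stack, other)
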