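"""SMA estimation and group tests: closed-form oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import beeallometry as ba


def _gaussian_group(rng, n=30, slope=2.0, corr=0.8, mu_x=0.0, mu_y=0.0):
    """Bivariate Gaussian with population SMA slope `slope` (raw scale)."""
    x = rng.normal(0.0, 1.0, n)
    y = mu_y + corr * slope * (x - mu_x) + rng.normal(
        0.0, abs(slope) * math.sqrt(1 - corr * corr), n
    )
    return x + mu_x, y


class TestSmaFit:
    def test_exact_line_slope_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = ba.sma_fit(x, 2 * x, log=False)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)

    def test_raw_scale_hand_oracle(self):
        # slope = sign(r) * s_y / s_x and intercept = ybar - slope * xbar,
        # worked by hand for this 5-point set
        x = np.arange(1.0, 6.0)
        y = np.array([1.2, 1.9, 3.2, 3.8, 5.1])
        fit = ba.sma_fit(x, y, log=False)
        assert fit.slope == pytest.approx(0.9763, abs=2e-4)
        assert fit.intercept == pytest.approx(0.1110, abs=2e-4)

    def test_ci_brackets_slope(self, rng):
        x, y = _gaussian_group(rng, n=50)
        fit = ba.sma_fit(np.exp(x), np.exp(y))  # log=True path
        assert fit.slope_ci_low < fit.slope < fit.slope_ci_high

    def test_robust_resists_gross_outlier(self, rng):
        x = rng.uniform(1, 5, 40)
        y = 2.0 * x * np.exp(rng.normal(0, 0.05, 40))
        clean = ba.sma_fit(x, y).slope
        xc, yc = np.append(x, 1.2), np.append(y, 60.0)
        classical = ba.sma_fit(xc, yc).slope
        robust = ba.sma_fit(xc, yc, robust=True).slope
        assert abs(robust - clean) / clean < 0.05
        assert abs(classical - clean) / clean > 0.05

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            ba.sma_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            ba.sma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], log=False)
        with pytest.raises(ValueError, match="positive"):
            ba.sma_fit([-1.0, 1.0, 2.0], [1.0, 2.0, 3.0])


@st.composite
def xy_datasets(draw):
    n = draw(st.integers(min_value=4, max_value=30))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    rng = np.random.default_rng(seed)
    x = rng.normal(0, draw(st.floats(0.2, 3.0)), n)
    y = draw(st.floats(-3.0, 3.0)) * x + rng.normal(0, draw(st.floats(0.1, 2.0)), n)
    # reject degenerate draws
    if np.var(x) == 0 or np.var(y) == 0:
        x = x + rng.normal(0, 1, n)
        y = y + rng.normal(0, 1, n)
    return x, y


class TestSmaProperties:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(xy_datasets())
    def test_closed_form_oracle(self, data):
        x, y = data
        fit = ba.sma_fit(x, y, log=False)
        r = np.corrcoef(x, y)[0, 1]
        expected = math.copysign(1.0, r if r != 0 else 1.0) * np.std(y, ddof=1) / np.std(x, ddof=1)
        assert fit.slope == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(xy_datasets())
    def test_reciprocal_under_axis_exchange(self, data):
        x, y = data
        b_xy = ba.sma_fit(x, y, log=False).slope
        b_yx = ba.sma_fit(y, x, log=False).slope
        assert b_xy * b_yx == pytest.approx(1.0, rel=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(xy_datasets(), st.floats(0.01, 50.0))
    def test_scale_equivariance(self, data, c):
        x, y = data
        b = ba.sma_fit(x, y, log=False).slope
        b_scaled = ba.sma_fit(x, c * y, log=False).slope
        assert b_scaled == pytest.approx(c * b, rel=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(xy_datasets())
    def test_sma_steeper_than_ols(self, data):
        x, y = data
        b_sma = ba.sma_fit(x, y, log=False).slope
        b_ols = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert abs(b_sma) >= abs(b_ols) - 1e-12


class TestSlopeEquals:
    def test_p_one_at_fitted_slope(self, rng):
        x, y = _gaussian_group(rng)
        fit = ba.sma_fit(x, y, log=False)
        res = ba.test_slope_equals(x, y, fit.slope, log=False)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert res.extra["b0_in_ci"] == 1.0

    def test_separation(self):
        x = np.linspace(1, 5, 30)
        res = ba.test_slope_equals(x, 2 * x, 1.0, log=False)
        assert res.p_value < 1e-10
        assert res.extra["b0_in_ci"] == 0.0

    def test_nominal_level_for_isometry(self):
        # true slope 1 (isometry), test b0 = 1: ~5% rejections
        rng = np.random.default_rng(77)
        rej = 0
        reps = 1000
        for _ in range(reps):
            x, y = _gaussian_group(rng, n=30, slope=1.0)
            rej += ba.test_slope_equals(x, y, 1.0, log=False).p_value < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestCommonSlope:
    def test_identical_groups_statistic_zero(self, rng):
        x, y = _gaussian_group(rng)
        groups = {g: (x.copy(), y.copy()) for g in "abc"}
        b, res = ba.test_common_slope(groups, log=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)
        assert b == pytest.approx(ba.sma_fit(x, y, log=False).slope, rel=1e-6)
        assert res.df == 2

    def test_detects_different_slopes(self, rng):
        groups = {
            "a": _gaussian_group(rng, n=60, slope=1.0),
            "b": _gaussian_group(rng, n=60, slope=2.0),
        }
        _, res = ba.test_common_slope(groups, log=False)
        assert res.p_value < 1e-4

    def test_degenerate_group_named(self, rng):
        x, y = _gaussian_group(rng)
        groups = {"fine": (x, y), "flat": (np.ones(10), np.arange(10.0))}
        with pytest.raises(ValueError, match="flat"):
            ba.test_common_slope(groups, log=False)


class TestCommonElevation:
    def test_identical_groups_statistic_zero(self, rng):
        x, y = _gaussian_group(rng)
        groups = {g: (x.copy(), y.copy()) for g in "abcd"}
        res = ba.test_common_elevation(groups, log=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.df == 3

    def test_large_shift_detected(self, rng):
        a = _gaussian_group(rng, n=40)
        x2, y2 = _gaussian_group(rng, n=40)
        groups = {"a": a, "b": (x2, y2 + 10.0)}  # ~10 SD elevation shift
        res = ba.test_common_elevation(groups, log=False)
        assert res.p_value < 1e-6
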