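import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pria import (
    CredibleSlopeScreener,
    DegenerateWindowError,
    FluorescenceTrace,
    ScreenConfig,
    TraceSimConfig,
    endpoint_slope,
    enumerate_interval_fits,
    fit_bias_for_slope,
    screen_credible_slope,
    simulate_trace,
    window_r2,
)
from oracle import brute_force_screen, literal_slope_sum


def _line(slope, bias, n, start=1):
    cycles = np.arange(start, start + n)
    return FluorescenceTrace(cycles, slope * cycles + bias)


class TestEndpointSlope:
    def test_exact_line(self):
        t = FluorescenceTrace.from_intensities([1, 3, 5, 7, 9])
        assert endpoint_slope(t, 1, 5) == 2.0

    def test_constant_trace_any_window(self):
        t = FluorescenceTrace.from_intensities([4.0] * 8)
        for i, j in [(1, 2), (2, 7), (1, 8)]:
            assert endpoint_slope(t, i, j) == 0.0

    def test_matches_literal_successive_difference_sum(self, rng):
        values = rng.normal(50, 10, size=20)
        t = FluorescenceTrace.from_intensities(values)
        for i in range(1, 20):
            for j in range(i + 1, 21):
                expected = literal_slope_sum(values, i - 1, j - 1)
                assert endpoint_slope(t, i, j) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_errors(self):
        t = FluorescenceTrace.from_intensities([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            endpoint_slope(t, 3, 2)
        with pytest.raises(IndexError):
            endpoint_slope(t, 1, 4)


class TestFitBiasForSlope:
    def test_perfect_fit_recovers_intercept(self):
        t = _line(2.0, 1.0, 10)
        bias, sse = fit_bias_for_slope(t, 1, 10, 2.0)
        assert bias == pytest.approx(1.0, abs=1e-12)
        assert sse == pytest.approx(0.0, abs=1e-18)

    def test_zero_slope_gives_window_mean(self, rng):
        values = rng.uniform(0, 10, size=12)
        t = FluorescenceTrace.from_intensities(values)
        bias, _ = fit_bias_for_slope(t, 3, 9, 0.0)
        assert bias == pytest.approx(values[2:9].mean(), rel=1e-12)

    def test_grid_search_oracle(self, rng):
        values = 3.0 * np.arange(1, 16) + rng.normal(0, 1.5, 15)
        t = FluorescenceTrace.from_intensities(values)
        slope = 2.7
        bias, sse = fit_bias_for_slope(t, 2, 14, slope)
        x, y = t.window(2, 14)
        grid = np.arange(bias - 1.0, bias + 1.0, 1e-4)
        sses = ((y[None, :] - (slope * x[None, :] + grid[:, None])) ** 2).sum(axis=1)
        assert abs(grid[np.argmin(sses)] - bias) <= 1e-4
        assert sse <= sses.min() + 1e-12

    def test_rejects_nonfinite_slope(self):
        t = FluorescenceTrace.from_intensities([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_bias_for_slope(t, 1, 3, math.inf)


class TestWindowR2:
    def test_perfect_line_is_one(self):
        t = _line(1.7, -4.0, 12)
        assert window_r2(t, 1, 12, 1.7, -4.0) == 1.0

    def test_mean_prediction_is_zero(self, rng):
        values = rng.uniform(0, 5, size=10)
        t = FluorescenceTrace.from_intensities(values)
        bias = values[1:9].mean()
        assert window_r2(t, 2, 9, 0.0, bias) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_sse_sst(self, rng):
        values = rng.normal(20, 4, size=15)
        t = FluorescenceTrace.from_intensities(values)
        slope, bias = 1.1, 18.0
        x, y = t.window(4, 13)
        sse = math.fsum((yy - (slope * xx + bias)) ** 2 for xx, yy in zip(x, y))
        sst = math.fsum((yy - math.fsum(y) / len(y)) ** 2 for yy in y)
        assert window_r2(t, 4, 13, slope, bias) == pytest.approx(
            1 - sse / sst, rel=1e-12
        )

    def test_constant_window_is_degenerate(self):
        t = FluorescenceTrace.from_intensities([5.0] * 6)
        with pytest.raises(DegenerateWindowError):
            window_r2(t, 1, 6, 0.0, 5.0)


class TestEnumerate:
    def test_twelve_cycle_trace_min_window_ten(self):
        t = _line(1.0, 0.0, 12)
        fits = enumerate_interval_fits(t, ScreenConfig(min_window=10))
        assert [(f.i, f.j) for f in fits] == [
            (1, 10), (1, 11), (1, 12), (2, 11), (2, 12), (3, 12),
        ]

    @pytest.mark.parametrize("m", [8, 12, 20])
    def test_count_matches_pair_formula(self, m, rng):
        t = FluorescenceTrace.from_intensities(rng.normal(size=m))
        fits = enumerate_interval_fits(t, ScreenConfig(min_window=3))
        assert len(fits) == (m - 2) * (m - 1) // 2

    def test_perfect_line_all_windows_unit_r2_same_slope(self):
        t = _line(3.5, 10.0, 15)
        for f in enumerate_interval_fits(t, ScreenConfig(min_window=5)):
            assert f.r2 == pytest.approx(1.0, abs=1e-12)
            assert f.slope == pytest.approx(3.5, rel=1e-12)
            assert f.sse == pytest.approx(0.0, abs=1e-12)

    def test_too_short_trace_raises(self):
        t = FluorescenceTrace.from_intensities([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="min_window"):
            enumerate_interval_fits(t, ScreenConfig(min_window=10))

    def test_constant_windows_get_nan_r2(self):
        values = np.concatenate([np.full(10, 2.0), np.arange(1, 11) + 2.0])
        t = FluorescenceTrace.from_intensities(values)
        fits = enumerate_interval_fits(t, ScreenConfig(min_window=5))
        flat = [f for f in fits if f.j <= 10]
        assert flat and all(math.isnan(f.r2) for f in flat)


class TestScreen:
    def test_global_perfect_line(self):
        t = _line(3.5, 2.0, 20)
        res = screen_credible_slope(t, ScreenConfig())
        assert res.credible
        assert res.best.slope == pytest.approx(3.5, rel=1e-12)
        # tie between equal slopes resolves to the longest window
        assert (res.best.i, res.best.j) == (1, 20)
        assert res.n_passing == res.n_candidates

    def test_composite_trace_finds_linear_phase(self):
        config = TraceSimConfig(
            n_cycles=40, baseline=20.0, base_slope=5.0, lag_cycles=10,
            plateau_cycle=30, noise_sd=0.25, seed=404,
        )
        t = simulate_trace(config)
        res = screen_credible_slope(t, ScreenConfig())
        assert res.credible
        assert res.best.slope == pytest.approx(5.0, rel=0.02)
        assert 10 <= res.best.i and res.best.j <= 30
        credible, best = brute_force_screen(t.cycles, t.intensities)
        assert credible
        assert (res.best.i, res.best.j) == (best[0], best[1])
        assert res.best.slope == pytest.approx(best[2], rel=1e-12)

    def test_white_noise_is_not_credible(self, rng):
        t = FluorescenceTrace.from_intensities(rng.normal(0, 1, size=40))
        res = screen_credible_slope(t, ScreenConfig())
        assert not res.credible
        assert res.n_passing == 0
        assert res.best is not None  # diagnostic best is still reported
        credible, _ = brute_force_screen(t.cycles, t.intensities)
        assert not credible

    def test_negative_trend_needs_flag(self):
        t = _line(-2.0, 100.0, 15)
        assert not screen_credible_slope(t, ScreenConfig()).credible
        res = screen_credible_slope(
            t, ScreenConfig(require_positive_slope=False)
        )
        assert res.credible
        assert res.best.slope == pytest.approx(-2.0, rel=1e-12)

    def test_monotone_in_threshold(self, rng):
        values = np.arange(1.0, 26.0) * 2 + rng.normal(0, 0.4, 25)
        t = FluorescenceTrace.from_intensities(values)
        slopes = []
        for thr in (0.9999, 0.999, 0.99, 0.9, 0.5):
            res = screen_credible_slope(t, ScreenConfig(r2_threshold=thr))
            slopes.append(res.best.slope if res.credible else -math.inf)
        assert slopes == sorted(slopes)


class TestScreenerEstimator:
    def test_sklearn_contract_and_transform(self):
        from sklearn.base import clone

        est = CredibleSlopeScreener(min_window=8)
        assert clone(est).get_params()["min_window"] == 8
        X = np.vstack(
            [
                2.0 * np.arange(1, 21) + 5.0,
                np.full(20, 7.0),  # constant well: nothing credible
            ]
        )
        out = est.fit(X).transform(X)
        assert out.shape == (2, 1)
        assert out[0, 0] == pytest.approx(2.0, rel=1e-12)
        assert np.isnan(out[1, 0])

    def test_screen_trace_matches_function(self, noisy_trace):
        est = CredibleSlopeScreener()
        assert (
            est.screen_trace(noisy_trace)
            == screen_credible_slope(noisy_trace, ScreenConfig())
        )

    def test_cycle_count_mismatch_rejected(self):
        est = CredibleSlopeScreener()
        est.fit(np.arange(30.0)[None, :])
        with pytest.raises(ValueError, match="cycles"):
            est.transform(np.arange(20.0)[None, :])


@st.composite
def integer_traces(draw, min_len=12, max_len=24):
    n = draw(st.integers(min_len, max_len))
    values = draw(
        st.lists(st.integers(-50, 50), min_size=n, max_size=n).map(
            lambda v: np.asarray(v, dtype=float)
        )
    )
    return FluorescenceTrace.from_intensities(values)


@given(
    integer_traces(),
    st.floats(0.1, 10.0),
    st.floats(-100.0, 100.0),
)
def test_affine_invariance_of_screening(trace, c, d):
    """y → c·y + d scales slopes by c but leaves R² and selection alone."""
    scaled = FluorescenceTrace(trace.cycles, c * trace.intensities + d)
    config = ScreenConfig(min_window=6)
    fits = enumerate_interval_fits(trace, config)
    fits_scaled = enumerate_interval_fits(scaled, config)
    for f, g in zip(fits, fits_scaled):
        assert (f.i, f.j) == (g.i, g.j)
        assert g.slope == pytest.approx(c * f.slope, rel=1e-9, abs=1e-9)
        if math.isnan(f.r2):
            assert math.isnan(g.r2)
        else:
            assert g.r2 == pytest.approx(f.r2, rel=1e-9, abs=1e-9)
    res, res_scaled = (
        screen_credible_slope(trace, config),
        screen_credible_slope(scaled, config),
    )
    assert res.credible == res_scaled.credible
    if res.best is not None:
        assert (res.best.i, res.best.j) == (res_scaled.best.i, res_scaled.best.j)


@given(integer_traces())
def test_ols_r2_never_below_endpoint_r2(trace):
    config_e = ScreenConfig(min_window=6, slope_mode="endpoint")
    config_o = ScreenConfig(min_window=6, slope_mode="ols")
    for fe, fo in zip(
        enumerate_interval_fits(trace, config_e),
        enumerate_interval_fits(trace, config_o),
    ):
        if math.isnan(fe.r2):
            continue
        assert fo.r2 >= fe.r2 - 1e-12
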