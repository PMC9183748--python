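"""Smoothing/fluctuation decomposition, stability classes, indoor-outdoor."""

import numpy as np
import pandas as pd
import pytest

from librisk.climate import (
    centred_moving_average,
    classify_gradient,
    fluctuation_histogram,
    monthly_indoor_outdoor,
    vertical_stability,
)
from librisk.ingest import HygroSeries

from conftest import make_series


class TestCentredMovingAverage:
    def test_constant_series_zero_residuals(self):
        s = make_series(np.full(40 * 96, 21.0), step_minutes=15.0)
        sm = centred_moving_average(s)
        f = sm.frame.dropna()
        assert len(f)
        np.testing.assert_allclose(f["T_24h"], 21.0)
        np.testing.assert_allclose(f["dT_24h"], 0.0, atol=1e-12)
        np.testing.assert_allclose(f["dRH_30d"], 0.0, atol=1e-12)

    def test_thirty_day_window_trims_fifteen_days_each_end(self):
        s = make_series(np.full(70 * 24, 20.0), step_minutes=60.0)
        sm = centred_moving_average(s)
        defined = sm.frame["RH_30d"].dropna()
        t0, t1 = s.span
        assert defined.index[0] >= t0 + pd.Timedelta(days=15)
        assert defined.index[-1] <= t1 - pd.Timedelta(days=15)

    def test_full_period_sinusoid_lands_in_residual(self):
        """A pure 1-day sinusoid averages to ~its mean over a 24-h window,
        so the residual carries (almost all of) the oscillation."""
        n = 40 * 96
        hours = np.arange(n) * 0.25
        T = 20.0 + 2.0 * np.sin(2 * np.pi * hours / 24.0)
        s = make_series(T, step_minutes=15.0)
        sm = centred_moving_average(s)
        f = sm.frame.dropna(subset=["T_24h"])
        np.testing.assert_allclose(f["T_24h"], 20.0, atol=0.1)
        resid = f["dT_24h"]
        orig = f["T"] - 20.0
        assert np.abs(resid - orig).max() < 0.1

    def test_shift_equivariance(self):
        rng = np.random.default_rng(4)
        base = 20 + rng.standard_normal(35 * 24)
        s1 = make_series(base, step_minutes=60.0)
        s2 = make_series(base + 7.5, step_minutes=60.0)
        f1 = centred_moving_average(s1).frame
        f2 = centred_moving_average(s2).frame
        np.testing.assert_allclose(f2["T_24h"], f1["T_24h"] + 7.5, atol=1e-9)
        np.testing.assert_allclose(f2["dT_24h"], f1["dT_24h"], atol=1e-9)

    def test_decomposition_identity(self, smoothed_year):
        f = smoothed_year.frame.dropna(subset=["T_24h", "RH_30d"])
        np.testing.assert_allclose(f["T_24h"] + f["dT_24h"], f["T"], atol=1e-9)
        np.testing.assert_allclose(f["RH_30d"] + f["dRH_30d"], f["RH"], atol=1e-9)

    def test_window_longer_than_span_rejected(self):
        s = make_series(np.full(24, 20.0), step_minutes=60.0)
        with pytest.raises(ValueError, match="span"):
            centred_moving_average(s)


class TestVerticalStability:
    def test_cold_ceiling_is_unstable(self):
        up = make_series([19.5] * 4, step_minutes=60.0)
        lo = make_series([20.0] * 4, step_minutes=60.0)
        out = vertical_stability(up, lo, dz=10.0)
        assert (out["stability"] == "unstable").all()
        np.testing.assert_allclose(out["gradient"], -0.5)

    def test_isothermal_is_neutral(self):
        up = make_series([20.0] * 4, step_minutes=60.0)
        lo = make_series([20.0] * 4, step_minutes=60.0)
        out = vertical_stability(up, lo, dz=10.0)
        assert (out["stability"] == "neutral").all()

    def test_warm_ceiling_is_stable(self):
        up = make_series([26.0] * 4, step_minutes=60.0)
        lo = make_series([24.0] * 4, step_minutes=60.0)
        out = vertical_stability(up, lo, dz=10.0)
        assert (out["stability"] == "stable").all()
        np.testing.assert_allclose(out["gradient"], 2.0)

    def test_classes_partition_all_records(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(-1, 1, 500)
        classes = classify_gradient(g)
        assert set(classes) <= {"unstable", "neutral", "stable"}
        assert len(classes) == 500

    def test_misaligned_series_rejected(self):
        up = make_series([20.0] * 4, step_minutes=60.0)
        lo = make_series([20.0] * 4, start="2020-01-01 00:30", step_minutes=60.0)
        with pytest.raises(ValueError, match="aligned"):
            vertical_stability(up, lo, dz=10.0)

    def test_dz_must_be_positive(self):
        s = make_series([20.0] * 4, step_minutes=60.0)
        with pytest.raises(ValueError):
            vertical_stability(s, s, dz=0.0)


def _year_pair(transform):
    idx_n = 366 * 24
    rng = np.random.default_rng(9)
    hours = np.arange(idx_n)
    out_T = 15 + 8 * np.sin(2 * np.pi * hours / (365.25 * 24)) + rng.normal(0, 0.5, idx_n)
    s_out = make_series(out_T, start="2020-01-01", step_minutes=60.0, probe_id="out")
    s_in = make_series(transform(out_T), start="2020-01-01", step_minutes=60.0, probe_id="in")
    return s_in, s_out


class TestMonthlyIndoorOutdoor:
    def test_identity_gives_unit_slope(self):
        s_in, s_out = _year_pair(lambda x: x)
        fit = monthly_indoor_outdoor(s_in, s_out)
        assert fit["slope"] == pytest.approx(1.0, abs=1e-9)
        assert fit["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_appears_in_intercept(self):
        s_in, s_out = _year_pair(lambda x: x + 3.0)
        fit = monthly_indoor_outdoor(s_in, s_out)
        assert fit["slope"] == pytest.approx(1.0, abs=1e-9)
        assert fit["intercept"] == pytest.approx(3.0, abs=1e-9)

    def test_damped_amplitude_halves_slope(self):
        s_in, s_out = _year_pair(lambda x: 10 + 0.5 * x)
        fit = monthly_indoor_outdoor(s_in, s_out)
        assert fit["slope"] == pytest.approx(0.5, abs=1e-9)

    def test_too_few_months_rejected(self):
        s = make_series(np.full(24, 20.0), step_minutes=60.0)
        with pytest.raises(ValueError, match="months"):
            monthly_indoor_outdoor(s, s)


class TestFluctuationHistogram:
    def test_all_zero_residuals_single_bin(self):
        h = fluctuation_histogram(pd.Series(np.zeros(100)), bin_width=0.5)
        assert h["counts"].sum() == 100
        assert (h["counts"] > 0).sum() == 1

    def test_alternating_residuals_symmetric(self):
        r = pd.Series(np.tile([1.0, -1.0], 50))
        h = fluctuation_histogram(r, bin_width=0.5)
        nz = h["counts"][h["counts"] > 0]
        assert list(nz) == [50, 50]

    def test_gaussian_central_86_matches_normal_quantile(self):
        rng = np.random.default_rng(7)
        r = pd.Series(rng.normal(0, 0.5, 40000))
        h = fluctuation_histogram(r, bin_width=0.1)
        # Φ⁻¹(0.93)·σ = 1.4758·0.5 = 0.7379
        assert h["half_spread_86"] == pytest.approx(0.7379, abs=0.02)
        assert h["counts"].sum() == 40000

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fluctuation_histogram(pd.Series(dtype=float))
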