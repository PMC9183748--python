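"""Hydrolysis dose-response, expected lifetime, TWEL and isochrones."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from librisk.chemical import (
    DEFAULT_DOSE_RESPONSE,
    PAPER_TYPES,
    PaperType,
    chemical_risk_index,
    degradation_rate,
    expected_lifetime,
    isochrone_grid,
    seasonal_twel,
    twel,
)

MODEL = DEFAULT_DOSE_RESPONSE

#: Hand-evaluated regression pin of the shipped coefficient set at
#: pH 5.2, 20 °C, 50 %RH: exp(36.66 − 0.244·5.2 + 0.035·50 − Ea/(R·293.15)).
K_REFERENCE = 8.44765275758139e-06


class TestDegradationRate:
    def test_arrhenius_monotone_in_T(self):
        assert degradation_rate(MODEL, 5.2, 30.0, 50.0) > degradation_rate(
            MODEL, 5.2, 20.0, 50.0
        )

    def test_acidity_ordering(self):
        assert degradation_rate(MODEL, 7.6, 20.0, 50.0) < degradation_rate(
            MODEL, 5.2, 20.0, 50.0
        )

    def test_increasing_in_RH(self):
        assert degradation_rate(MODEL, 6.4, 20.0, 60.0) > degradation_rate(
            MODEL, 6.4, 20.0, 40.0
        )

    def test_regression_pin_of_shipped_coefficients(self):
        assert degradation_rate(MODEL, 5.2, 20.0, 50.0) == pytest.approx(
            K_REFERENCE, rel=1e-12
        )

    def test_outside_validity_domain_warns(self):
        with pytest.warns(UserWarning, match="validity domain"):
            degradation_rate(MODEL, 5.2, 55.0, 50.0)

    def test_missing_coefficient_is_config_error(self):
        broken = dataclasses.replace(MODEL, Ea=None)
        with pytest.raises(ValueError, match="missing"):
            degradation_rate(broken, 5.2, 20.0, 50.0)


class TestExpectedLifetime:
    def test_el_vanishes_as_dp0_approaches_critical(self):
        p = PaperType("edge", pH=6.0, DP0=300.5, DP_crit=300.0)
        assert expected_lifetime(MODEL, p, 20.0, 50.0) < 1.0

    def test_halving_k_doubles_el(self):
        p = PAPER_TYPES["acidic"]
        slower = dataclasses.replace(MODEL, lnA=MODEL.lnA - np.log(2.0))
        assert expected_lifetime(slower, p, 20.0, 50.0) == pytest.approx(
            2.0 * expected_lifetime(MODEL, p, 20.0, 50.0), rel=1e-12
        )

    @pytest.mark.parametrize("T,RH", [(18.0, 45.0), (24.0, 55.0), (30.0, 60.0)])
    def test_el_ordering_in_dp0_at_fixed_climate(self, T, RH):
        els = [
            expected_lifetime(MODEL, PaperType("p", 5.0, dp0), T, RH)
            for dp0 in (600.0, 1500.0, 2000.0)
        ]
        assert els[0] < els[1] < els[2]

    @pytest.mark.parametrize("T,RH", [(18.0, 45.0), (26.0, 60.0)])
    def test_el_ordering_across_paper_classes(self, T, RH):
        el = {
            name: expected_lifetime(MODEL, PAPER_TYPES[name], T, RH)
            for name in ("acidic", "rag", "contemporary")
        }
        assert el["acidic"] < el["rag"] < el["contemporary"]

    def test_dp0_below_critical_rejected(self):
        with pytest.raises(ValueError):
            PaperType("bad", pH=6.0, DP0=250.0, DP_crit=300.0)


class TestTWEL:
    def test_constant_climate_twel_equals_el(self):
        assert twel(np.full(100, 500.0)).TWEL == pytest.approx(500.0, rel=1e-12)

    def test_two_value_harmonic_mean(self):
        assert twel(np.array([200.0, 600.0])).TWEL == pytest.approx(300.0, rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=1.0, max_value=1e5), min_size=1, max_size=40))
    def test_harmonic_below_arithmetic(self, els):
        t = twel(np.array(els)).TWEL
        assert t <= np.mean(els) * (1 + 1e-9)
        assert min(els) * (1 - 1e-9) <= t <= max(els) * (1 + 1e-9)

    def test_yearly_twel_nested_in_seasonal_range(self):
        idx = pd.date_range("2020-01-01", "2020-12-31 23:00", freq="1h")
        T = 20 + 7 * np.sin(2 * np.pi * (idx.dayofyear - 100) / 365.25)
        el = pd.Series(
            expected_lifetime(MODEL, PAPER_TYPES["rag"], T.to_numpy(), 50.0), index=idx
        )
        year = twel(el).TWEL
        seasons = [r.TWEL for r in seasonal_twel(el)]
        assert len(seasons) == 4
        assert min(seasons) <= year <= max(seasons)

    def test_smoothed_inputs_never_farther_from_constant_el(self):
        """Jensen gap: averaging the climate first can only move TWEL
        toward the constant-climate EL."""
        idx = pd.date_range("2020-01-01", periods=30 * 24, freq="1h")
        raw_T = pd.Series(20 + 5 * np.sin(np.arange(len(idx)) * 2 * np.pi / 24), index=idx)
        smooth_T = raw_T.rolling(24, center=True, min_periods=24).mean().dropna()
        p = PAPER_TYPES["acidic"]
        el_const = expected_lifetime(MODEL, p, 20.0, 50.0)
        tw_raw = twel(expected_lifetime(MODEL, p, raw_T.to_numpy(), 50.0)).TWEL
        tw_smooth = twel(expected_lifetime(MODEL, p, smooth_T.to_numpy(), 50.0)).TWEL
        assert abs(tw_smooth - el_const) <= abs(tw_raw - el_const)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            twel(np.array([]))


class TestIsochronesAndRiskIndex:
    def test_el_decreases_with_T_along_fixed_RH(self):
        g = isochrone_grid(MODEL, PAPER_TYPES["rag"], n=41)
        assert (np.diff(g["EL"], axis=1) < 0).all()  # columns: increasing T

    def test_500y_level_splits_grid_into_two_connected_regions(self):
        g = isochrone_grid(MODEL, PAPER_TYPES["acidic"], n=61)
        below = g["EL"] < 500.0
        # along every fixed-RH row, once EL drops below the level it stays below
        for row in below:
            flips = np.diff(row.astype(int))
            assert (flips >= 0).all()

    def test_grid_reproduces_rate_fixture(self):
        g = isochrone_grid(MODEL, PaperType("acidic", 5.2, 826.3),
                           T_range=(20.0, 30.0), RH_range=(50.0, 60.0), n=11)
        el_direct = (1 / 300.0 - 1 / 826.3) / K_REFERENCE
        assert g["EL"][0, 0] == pytest.approx(el_direct, rel=1e-12)

    def test_risk_index_extremes(self):
        assert chemical_risk_index(np.full(10, 900.0)) == 0.0
        assert chemical_risk_index(np.full(10, 100.0)) == 100.0

    def test_risk_index_counting_oracle(self):
        el = np.r_[np.full(120, 300.0), np.full(245, 800.0)]
        assert chemical_risk_index(el) == pytest.approx(100 * 120 / 365, rel=1e-12)
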