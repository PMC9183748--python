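"""Logger-series ingest, validity flagging, completeness and psychrometrics."""

import numpy as np
import pandas as pd
import pytest

from librisk.ingest import (
    CsvDialect,
    HygroSeries,
    completeness_index,
    mixing_ratio,
    read_hygro_series,
    resample,
    write_hygro_series,
)

from conftest import make_series


def _write_csv(tmp_path, text, name="probe.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_well_formed_file_reads_back(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "timestamp,T,RH\n"
            "2020-01-01 00:00,20.0,45.0\n"
            "2020-01-01 00:15,20.5,46.0\n"
            "2020-01-01 00:30,21.0,47.0\n",
        )
        s = read_hygro_series(p)
        assert len(s) == 3
        assert s.step_minutes == 15.0
        assert s.data["valid"].all()
        np.testing.assert_allclose(s.data["T"], [20.0, 20.5, 21.0])

    def test_out_of_range_rh_flagged_not_clipped(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "timestamp;T;RH\n2020-01-01 00:00;20;45\n"
            "2020-01-01 00:15;20;134\n2020-01-01 00:30;20;50\n",
        )
        s = read_hygro_series(p, CsvDialect(sep=";"))
        assert list(s.data["valid"]) == [True, False, True]
        assert s.data["RH"].iloc[1] == 134.0  # retained raw, not clipped
        assert completeness_index(s).valid_n == 2

    def test_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        s = make_series(20 + rng.standard_normal(50), 40 + 10 * rng.random(50))
        out = tmp_path / "rt.csv"
        write_hygro_series(s, out)
        s2 = read_hygro_series(out, CsvDialect(sep=","))
        np.testing.assert_array_equal(s.data["T"].to_numpy(), s2.data["T"].to_numpy())
        np.testing.assert_array_equal(s.data["RH"].to_numpy(), s2.data["RH"].to_numpy())
        assert s.data.index.equals(s2.data.index)

    def test_unparseable_timestamp_names_row(self, tmp_path):
        p = _write_csv(
            tmp_path, "timestamp,T,RH\n2020-01-01 00:00,20,45\nnot-a-date,20,45\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_hygro_series(p)

    def test_duplicate_timestamps_rejected(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "timestamp,T,RH\n2020-01-01 00:00,20,45\n2020-01-01 00:00,21,46\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_hygro_series(p)

    def test_missing_declared_column(self, tmp_path):
        p = _write_csv(tmp_path, "timestamp,temp,RH\n2020-01-01,20,45\n")
        with pytest.raises(ValueError, match="'T'"):
            read_hygro_series(p)


class TestCompleteness:
    def test_gapless_series_has_coi_one(self):
        s = make_series(np.full(96, 20.0))
        assert completeness_index(s).CoI == 1.0

    def test_half_missing_gives_half(self):
        s = make_series(np.full(100, 20.0))
        t0, t1 = s.span
        s2 = HygroSeries("P", s.data.drop(s.data.index[10:60]), 15.0)
        rep = completeness_index(s2, window=(t0, t1))
        assert rep.CoI == 0.5

    @pytest.mark.parametrize("k", [1, 7, 33])
    def test_random_deletion_counting_oracle(self, k):
        n = 200
        s = make_series(np.full(n, 20.0))
        t0, t1 = s.span
        rng = np.random.default_rng(k)
        drop = rng.choice(np.arange(1, n - 1), size=k, replace=False)
        s2 = HygroSeries("P", s.data.drop(s.data.index[drop]), 15.0)
        assert completeness_index(s2, window=(t0, t1)).CoI == (n - k) / n

    def test_empty_window_rejected(self):
        s = make_series(np.full(10, 20.0))
        t0, _ = s.span
        with pytest.raises(ValueError):
            completeness_index(s, window=(t0, t0 - pd.Timedelta("1h")))

    def test_concatenated_windows_weighted_mean(self):
        """CoI over a union window is the expected-count-weighted mean."""
        n = 192
        s = make_series(np.full(n, 20.0))
        idx = s.data.index
        mid = idx[n // 2]
        drop = np.arange(10, 40)
        s2 = HygroSeries("P", s.data.drop(idx[drop]), 15.0)
        r1 = completeness_index(s2, (idx[0], mid))
        r2 = completeness_index(s2, (mid + pd.Timedelta(minutes=15), idx[-1]))
        r_all = completeness_index(s2, (idx[0], idx[-1]))
        weighted = (r1.CoI * r1.expected_n + r2.CoI * r2.expected_n) / (
            r1.expected_n + r2.expected_n
        )
        assert r_all.CoI == pytest.approx(weighted, abs=1e-12)


class TestMixingRatio:
    def test_zero_rh_gives_zero(self):
        for T in (-10.0, 0.0, 25.0):
            assert mixing_ratio(T, 0.0) == 0.0

    def test_magnus_oracle_at_20C_50pct(self):
        # independent arithmetic: e_s = 6.112·exp(17.62·20/263.12) = 23.33 hPa
        e = 0.5 * 6.112 * np.exp(17.62 * 20.0 / (243.12 + 20.0))
        expected = 622.0 * e / (1013.25 - e)
        got = mixing_ratio(20.0, 50.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(7.25, abs=0.02)

    def test_monotone_in_T_and_RH(self):
        assert mixing_ratio(25, 50) > mixing_ratio(20, 50)
        assert mixing_ratio(20, 60) > mixing_ratio(20, 50)

    def test_pressure_below_vapour_pressure_rejected(self):
        with pytest.raises(ValueError, match="pressure"):
            mixing_ratio(50.0, 100.0, pressure_hPa=100.0)


class TestResample:
    def test_constant_series_preserved(self):
        s = make_series(np.full(8, 21.0))
        r = resample(s, 60)
        assert (r.data["T"] == 21.0).all()
        assert r.step_minutes == 60.0

    def test_hourly_mean_arithmetic(self):
        s = make_series([20.0, 20.0, 22.0, 22.0])
        r = resample(s, 60)
        assert r.data["T"].iloc[0] == 21.0

    def test_gap_propagates_under_full_coverage_rule(self):
        vals = np.full(8, 20.0)
        rh = np.full(8, 50.0)
        rh[2] = 150.0  # invalid → block incomplete
        s = make_series(vals, rh)
        r = resample(s, 60, min_coverage=1.0)
        assert np.isnan(r.data["T"].iloc[0])
        assert not np.isnan(r.data["T"].iloc[1])

    def test_non_multiple_step_rejected(self):
        s = make_series(np.full(8, 20.0))
        with pytest.raises(ValueError, match="multiple"):
            resample(s, 40)
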