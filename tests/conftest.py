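import numpy as np
import pandas as pd
import pytest

from librisk import ClimateScenario, HygroSeries, generate_climate
from librisk.climate import SmoothedSeries, centred_moving_average


def make_series(values_T, values_RH=None, start="2020-01-01", step_minutes=15.0,
                probe_id="P"):
    """Small HygroSeries builder used across the suite."""
    T = np.asarray(values_T, dtype=float)
    RH = np.full_like(T, 50.0) if values_RH is None else np.asarray(values_RH, dtype=float)
    idx = pd.date_range(start, periods=len(T), freq=pd.Timedelta(minutes=step_minutes))
    return HygroSeries(probe_id, pd.DataFrame({"T": T, "RH": RH}, index=idx), step_minutes)


def make_smoothed(dRH_resid, RH_level=50.0, start="2020-01-01", step_minutes=60.0):
    """SmoothedSeries with a prescribed fluctuation sample (band-oracle input)."""
    r = np.asarray(dRH_resid, dtype=float)
    idx = pd.date_range(start, periods=len(r), freq=pd.Timedelta(minutes=step_minutes))
    frame = pd.DataFrame(
        {
            "T": 20.0,
            "RH": RH_level + r,
            "T_24h": 20.0,
            "RH_30d": RH_level,
            "dT_24h": 0.0,
            "dRH_30d": r,
        },
        index=idx,
    )
    return SmoothedSeries("P", frame, pd.Timedelta("24h"), pd.Timedelta("30d"))


@pytest.fixture(scope="session")
def scenario():
    return ClimateScenario(seed=11)


@pytest.fixture(scope="session")
def campaign(scenario):
    """One synthetic year (hourly, 380 d to survive the 30-day edge trim)."""
    probes, outdoor = generate_climate(scenario, start="2019-08-01",
                                       span_days=380.0, step_minutes=60.0)
    return probes, outdoor


@pytest.fixture(scope="session")
def smoothed_year(campaign):
    probes, _ = campaign
    return centred_moving_average(probes["RHT1"])
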