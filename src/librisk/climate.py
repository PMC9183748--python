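"""Indoor-climate characterisation: response-time smoothing, fluctuation
decomposition, vertical air-stability classification and indoor–outdoor
comparison.

Hygroscopic collections respond slowly to the ambient climate, so the
analysis separates each variable into a seasonal level and short-term
fluctuations using centred moving averages matched to the response time of
densely shelved paper books: 24 h for temperature and 30 days for relative
humidity. The residuals ΔT₂₄ₕ = T − T₂₄ₕ and ΔRH₃₀d = RH − RH₃₀d are the
fluctuations the collection actually feels, and feed both the mechanical
tolerance band and the chemical lifetime calculations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ingest import HygroSeries

__all__ = [
    "SmoothedSeries",
    "StabilityRecord",
    "centred_moving_average",
    "vertical_stability",
    "monthly_indoor_outdoor",
    "fluctuation_histogram",
]

#: Dry adiabatic vertical temperature gradient, °C per 10 m.
ADIABATIC_GRADIENT = -0.1


@dataclass
class SmoothedSeries:
    """Seasonal levels and short-term fluctuations for one probe.

    ``frame`` holds columns T, RH, T_24h, RH_30d, dT_24h, dRH_30d; the
    decomposition identity X = X_smoothed + residual holds wherever both are
    defined. The leading and trailing half-windows (15 days for RH_30d) are
    trimmed: the centred average is undefined there.
    """

    probe_id: str
    frame: pd.DataFrame
    window_T: pd.Timedelta
    window_RH: pd.Timedelta

    @property
    def edge_trim(self) -> tuple[pd.Timedelta, pd.Timedelta]:
        return self.window_RH / 2, self.window_RH / 2


def _centred_mean(x: pd.Series, window: pd.Timedelta, step: pd.Timedelta,
                  min_coverage: float) -> pd.Series:
    n = int(round(window / step))
    if n < 1:
        raise ValueError("window shorter than the sampling step")
    min_periods = max(1, int(np.ceil(min_coverage * n)))
    sm_ = x.rolling(window=n, center=True, min_periods=min_periods).mean()
    # trim half-window at each edge: a centred average is not defined there
    half = window / 2
    idx = x.index
    sm_[(idx < idx[0] + half) | (idx > idx[-1] - half)] = np.nan
    return sm_


def centred_moving_average(
    series: HygroSeries,
    window_T: str | pd.Timedelta = "24h",
    window_RH: str | pd.Timedelta = "30d",
    min_coverage: float = 0.9,
) -> SmoothedSeries:
    """Decompose T and RH into centred moving averages and residuals.

    The average at each timestamp is taken over a window centred on it and
    is undefined where fewer than ``min_coverage`` of the window's records
    are valid (gaps must not bias seasonal levels) or where the window
    overruns the series span (edges trimmed by half a window).
    """
    window_T = pd.Timedelta(window_T)
    window_RH = pd.Timedelta(window_RH)
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    d = series.data
    span = d.index[-1] - d.index[0]
    if window_RH > span or window_T > span:
        raise ValueError("smoothing window longer than the series span")
    step = pd.Timedelta(minutes=series.step_minutes)
    T = d["T"].where(d["valid"])
    RH = d["RH"].where(d["valid"])
    t24 = _centred_mean(T, window_T, step, min_coverage)
    rh30 = _centred_mean(RH, window_RH, step, min_coverage)
    frame = pd.DataFrame(
        {
            "T": T,
            "RH": RH,
            "T_24h": t24,
            "RH_30d": rh30,
            "dT_24h": T - t24,
            "dRH_30d": RH - rh30,
        }
    )
    return SmoothedSeries(series.probe_id, frame, window_T, window_RH)


@dataclass
class StabilityRecord:
    """Vertical temperature gradient (°C/10 m) and its buoyancy class."""

    timestamp: pd.Timestamp
    gradient: float
    stability: Literal["unstable", "neutral", "stable"]


def classify_gradient(
    gradient: np.ndarray,
    threshold: float = ADIABATIC_GRADIENT,
    tolerance: float = 0.05,
) -> np.ndarray:
    """Class per gradient g (°C/10 m, positive = warmer above).

    unstable: g below the adiabatic reference beyond tolerance (air parcel
    rises — temperature falls with height faster than adiabatic);
    neutral: |g| within tolerance of zero (indistinguishable from no
    layering at instrument resolution); stable otherwise (warm air aloft).
    """
    g = np.asarray(gradient, dtype=float)
    out = np.where(
        g < threshold - tolerance,
        "unstable",
        np.where(np.abs(g) <= tolerance, "neutral", "stable"),
    )
    return out


def vertical_stability(
    T_upper: HygroSeries,
    T_lower: HygroSeries,
    dz: float,
    threshold: float = ADIABATIC_GRADIENT,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Gradient (T_upper − T_lower)/dz rescaled to °C/10 m plus class.

    Series must share timestamps exactly; every aligned record with both
    temperatures valid receives a class (the classes partition the records).
    """
    if dz <= 0:
        raise ValueError("vertical separation dz must be > 0")
    du, dl = T_upper.data, T_lower.data
    if not du.index.equals(dl.index):
        raise ValueError(
            f"probes {T_upper.probe_id!r} and {T_lower.probe_id!r} are not "
            "aligned on the same timestamps"
        )
    tu = du["T"].where(du["valid"])
    tl = dl["T"].where(dl["valid"])
    g = (tu - tl) / dz * 10.0
    ok = g.notna()
    out = pd.DataFrame({"gradient": g})
    out["stability"] = pd.array([None] * len(out), dtype="object")
    out.loc[ok, "stability"] = classify_gradient(g[ok].to_numpy(), threshold, tolerance)
    return out


def monthly_indoor_outdoor(
    series_in: HygroSeries,
    series_out: HygroSeries,
    variable: str = "T",
    min_coverage: float = 0.8,
) -> dict:
    """Paired calendar-month means and the OLS line through them.

    Months are retained only when both series have at least ``min_coverage``
    of their expected records valid; the slope/intercept come from ordinary
    least squares of indoor on outdoor monthly means.
    """
    pairs = []
    for s in (series_in, series_out):
        if variable not in s.data.columns:
            raise ValueError(f"variable {variable!r} not present in probe {s.probe_id!r}")
        d = s.data
        vals = d[variable].where(d["valid"])
        per = vals.groupby(d.index.to_period("M"))
        counts = per.count()
        expected = per.size().index.map(
            lambda p: int(
                (min(p.end_time, d.index[-1]) - max(p.start_time, d.index[0]))
                / pd.Timedelta(minutes=s.step_minutes)
            )
            + 1
        )
        means = per.mean()
        means[counts < min_coverage * np.asarray(expected)] = np.nan
        pairs.append(means)
    joined = pd.concat(pairs, axis=1, join="inner", keys=["indoor", "outdoor"]).dropna()
    if len(joined) < 2:
        raise ValueError("need at least 2 overlapping months with sufficient coverage")
    X = sm.add_constant(joined["outdoor"].to_numpy())
    fit = sm.OLS(joined["indoor"].to_numpy(), X).fit()
    return {
        "months": joined,
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
    }


def fluctuation_histogram(residuals: pd.Series, bin_width: float = 0.2) -> dict:
    """Frequency table of short-term fluctuations plus a spread summary.

    The spread summary is the central 86 % interval (7th–93rd percentiles,
    the same quantile mass used by the mechanical tolerance band).
    """
    x = np.asarray(residuals.dropna(), dtype=float)
    if x.size == 0:
        raise ValueError("no defined residuals to histogram")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    q07, q93 = np.quantile(x, [0.07, 0.93])
    return {
        "counts": counts,
        "bin_edges": edges,
        "n": int(x.size),
        "central_86": (float(q07), float(q93)),
        "half_spread_86": float((q93 - q07) / 2),
    }
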