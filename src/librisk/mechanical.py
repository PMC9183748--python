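"""Mechanical risk: the historical-climate RH tolerance band of EN 15757:2010.

Hygroscopic objects acclimatise to the hygrothermal regime they have lived
in; dimensional stress arises from short-term RH excursions outside that
regime, not from the seasonal cycle itself. The standard therefore builds a
tolerance band around the 30-day seasonal RH level: the band limits are the
7th and 93rd percentiles of the short-term fluctuations ΔRH₃₀d, relaxed to
±10 percentage points whenever the fluctuations depart from the seasonal
level by less than that (percentile limits would then be unnecessarily
strict). The mechanical Risk Index is the percentage of time RH observations
fall outside the band; with percentile-based limits evaluated on their own
defining sample it cannot exceed 14 % (7 % of quantile mass per tail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .climate import SmoothedSeries

__all__ = ["ToleranceBand", "historical_climate_band", "mechanical_risk_index"]

#: EN 15757 fluctuation percentiles (lower, upper), in percent of the sample.
BAND_PERCENTILES = (7.0, 93.0)
#: Relaxed half-width (RH percentage points) applied when fluctuations are small.
BAND_RELAXATION = 10.0


@dataclass
class ToleranceBand:
    """Pointwise tolerable-RH band around the seasonal level RH_30d.

    ``method_per_limit`` records, per limit, whether the offset came from
    the fluctuation percentile or from the ±10 relaxation; offsets are
    constant, the band tracks RH_30d. Timestamps where RH_30d is undefined
    (trimmed edges, gaps) carry no band.
    """

    frame: pd.DataFrame  # columns: RH, RH_30d, lower, upper
    lower_offset: float
    upper_offset: float
    method_per_limit: dict[str, Literal["percentile", "plus_minus_10"]]
    percentiles: tuple[float, float] = BAND_PERCENTILES
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.lower_offset >= self.upper_offset:
            raise ValueError("band is empty: lower offset must be below upper offset")


def historical_climate_band(
    smoothed: SmoothedSeries,
    percentiles: tuple[float, float] = BAND_PERCENTILES,
    relaxation: float = BAND_RELAXATION,
) -> ToleranceBand:
    """Historical-climate RH band from the ΔRH₃₀d fluctuation distribution.

    Each limit independently takes whichever is wider: the fluctuation
    percentile or the ±``relaxation`` offset. Fluctuations within ±10 thus
    yield the relaxed band RH_30d ± 10; heavier-tailed fluctuation
    distributions keep their percentile limits. Quantiles use linear
    interpolation between order statistics.
    """
    f = smoothed.frame
    resid = f["dRH_30d"].dropna()
    if resid.empty:
        raise ValueError("no defined ΔRH_30d residuals: cannot build a band")
    span = f.index[-1] - f.index[0]
    if span < pd.Timedelta(days=360):
        warnings.warn(
            "historical-climate band built on less than one year of data; "
            "seasonal RH levels may be unrepresentative",
            stacklevel=2,
        )
    q_lo, q_hi = np.quantile(resid.to_numpy(), [p / 100 for p in percentiles])
    lower_offset = min(float(q_lo), -relaxation)
    upper_offset = max(float(q_hi), relaxation)
    method = {
        "lower": "percentile" if q_lo < -relaxation else "plus_minus_10",
        "upper": "percentile" if q_hi > relaxation else "plus_minus_10",
    }
    frame = pd.DataFrame(
        {
            "RH": f["RH"],
            "RH_30d": f["RH_30d"],
            "lower": f["RH_30d"] + lower_offset,
            "upper": f["RH_30d"] + upper_offset,
        }
    )
    return ToleranceBand(frame, lower_offset, upper_offset, method, percentiles)


def mechanical_risk_index(band: ToleranceBand, RH: pd.Series | None = None) -> float:
    """Percent of time RH observations lie outside the tolerance band.

    Evaluated only at timestamps where both the observation and the band are
    defined (trimmed edges are skipped, not extrapolated). When ``RH`` is
    omitted the band's own defining observations are used, in which case
    percentile-based limits bound the result at 14 %.
    """
    f = band.frame
    if RH is None:
        rh = f["RH"]
    else:
        rh = RH.reindex(f.index)
    ok = rh.notna() & f["lower"].notna() & f["upper"].notna()
    n = int(ok.sum())
    if n == 0:
        return 0.0
    outside = ((rh < f["lower"]) | (rh > f["upper"])) & ok
    return 100.0 * int(outside.sum()) / n
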