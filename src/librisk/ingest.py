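"""Reading, validation and quality scoring of hygrothermal logger series.

The universal input of the pipeline is a :class:`HygroSeries`: timestamped
air temperature (°C) and relative humidity (%) from a single probe sampling
at a fixed nominal step. Physically impossible values (RH outside [0, 100])
are *flagged*, never clipped or silently dropped, so that raw data remain
auditable while analyses see only valid records. Data quality over a window
is summarised by the Completeness Index (CoI), the fraction of expected
records at the nominal step that are present and valid.

Psychrometric support is limited to the mixing ratio MR (g water vapour per
kg dry air), derived from T and RH with a Magnus-form saturation vapour
pressure; MR is the temperature-independent humidity measure used for
indoor–outdoor moisture comparisons.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HygroSeries",
    "SensorMeta",
    "CompletenessReport",
    "CsvDialect",
    "read_hygro_series",
    "write_hygro_series",
    "completeness_index",
    "mixing_ratio",
    "saturation_vapour_pressure",
    "resample",
]

#: Default station pressure (hPa) used for mixing-ratio computations.
STANDARD_PRESSURE_HPA = 1013.25


@dataclass
class SensorMeta:
    """Probe deployment metadata.

    ``uncertainty_T`` (°C) and ``uncertainty_RH`` (%) are the declared
    instrument uncertainties (e.g. ±0.3 °C and ±0.8 % for the Pt100 /
    capacitive probes typical of heritage monitoring).
    """

    probe_id: str
    height_above_floor: float = 1.8
    level: int = 0
    uncertainty_T: float = 0.3
    uncertainty_RH: float = 0.8

    def __post_init__(self) -> None:
        if self.uncertainty_T <= 0 or self.uncertainty_RH <= 0:
            raise ValueError("sensor uncertainties must be > 0")


@dataclass
class CompletenessReport:
    """Completeness Index over a window: CoI = valid_n / expected_n."""

    window: tuple[pd.Timestamp, pd.Timestamp]
    expected_n: int
    valid_n: int

    @property
    def CoI(self) -> float:
        return self.valid_n / self.expected_n

    def __post_init__(self) -> None:
        if self.expected_n <= 0:
            raise ValueError("empty window: expected_n must be > 0")
        if not 0 <= self.valid_n <= self.expected_n:
            raise ValueError("valid_n must be within [0, expected_n]")


@dataclass
class HygroSeries:
    """Timestamped T/RH (optionally MR) record set for one probe.

    ``data`` is indexed by timestamp (local time, no DST arithmetic) with
    columns ``T`` (°C), ``RH`` (%), a boolean ``valid`` flag and optionally
    ``MR`` (g/kg). Invalid-but-parseable rows are retained with
    ``valid=False``; analysis accessors exclude them.
    """

    probe_id: str
    data: pd.DataFrame
    step_minutes: float
    meta: SensorMeta | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("HygroSeries.data must be indexed by timestamps")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate timestamp {dup} in probe {self.probe_id!r}")
        if not idx.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if self.step_minutes <= 0:
            raise ValueError("nominal step must be positive")
        if "valid" not in self.data.columns:
            self.data = self.data.assign(valid=_range_valid(self.data))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.data.index[0], self.data.index[-1]

    def valid_frame(self) -> pd.DataFrame:
        """The records usable for analysis (valid flag set, T and RH finite)."""
        d = self.data
        return d.loc[d["valid"] & d["T"].notna() & d["RH"].notna()]

    def with_mixing_ratio(self, pressure_hPa: float = STANDARD_PRESSURE_HPA) -> "HygroSeries":
        d = self.data.copy()
        mr = np.full(len(d), np.nan)
        ok = d["valid"].to_numpy() & d["T"].notna().to_numpy() & d["RH"].notna().to_numpy()
        mr[ok] = mixing_ratio(d["T"].to_numpy()[ok], d["RH"].to_numpy()[ok], pressure_hPa)
        d["MR"] = mr
        return HygroSeries(self.probe_id, d, self.step_minutes, self.meta)


def _range_valid(df: pd.DataFrame) -> pd.Series:
    rh = df["RH"]
    t = df["T"]
    return rh.notna() & t.notna() & (rh >= 0.0) & (rh <= 100.0)


@dataclass
class CsvDialect:
    """Column/format declaration for delimited-text logger exports.

    ``sep=None`` autodetects among comma/semicolon/tab. ``timestamp_format``
    ``None`` means ISO-8601.
    """

    sep: str | None = None
    timestamp_col: str = "timestamp"
    T_col: str = "T"
    RH_col: str = "RH"
    timestamp_format: str | None = None
    decimal: str = "."


def _sniff_sep(path: Path) -> str:
    sample = Path(path).read_text(encoding="utf-8")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_hygro_series(
    path: str | Path,
    dialect: CsvDialect | None = None,
    probe_id: str | None = None,
    step_minutes: float | None = None,
    meta: SensorMeta | None = None,
) -> HygroSeries:
    """Read a delimited-text T/RH series into a validated :class:`HygroSeries`.

    Out-of-range RH values are flagged invalid and retained. Unparseable
    timestamps raise a :class:`ValueError` naming the offending row;
    duplicate timestamps raise a data error. The nominal step is inferred
    from the modal timestamp difference when not declared.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = dialect or CsvDialect()
    sep = d.sep if d.sep is not None else _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, decimal=d.decimal, float_precision="round_trip")
    for col in (d.timestamp_col, d.T_col, d.RH_col):
        if col not in df.columns:
            raise ValueError(f"declared column {col!r} missing from {path.name}")
    ts = pd.to_datetime(df[d.timestamp_col], format=d.timestamp_format, errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(
            f"unparseable timestamp {df[d.timestamp_col].iloc[row]!r} at data row {row + 1}"
        )
    out = pd.DataFrame(
        {
            "T": pd.to_numeric(df[d.T_col], errors="coerce").to_numpy(),
            "RH": pd.to_numeric(df[d.RH_col], errors="coerce").to_numpy(),
        },
        index=pd.DatetimeIndex(ts, name="timestamp"),
    )
    if step_minutes is None:
        diffs = out.index.to_series().diff().dropna()
        if len(diffs):
            step_minutes = diffs.mode().iloc[0].total_seconds() / 60.0
        else:
            step_minutes = 15.0
    return HygroSeries(probe_id or path.stem, out, step_minutes, meta)


def write_hygro_series(series: HygroSeries, path: str | Path, sep: str = ",") -> None:
    """Write the normalised delimited-text form (lossless for valid records)."""
    cols = ["T", "RH"] + (["MR"] if "MR" in series.data.columns else []) + ["valid"]
    out = series.data[cols].copy()
    out.index.name = "timestamp"
    out.to_csv(path, sep=sep, float_format="%.17g")


def completeness_index(
    series: HygroSeries,
    window: tuple | None = None,
) -> CompletenessReport:
    """Completeness Index over ``window`` (default: the full series span).

    expected_n counts nominal-step slots from window start to window end
    inclusive; valid_n counts retained records flagged valid within the
    window. CoI = valid_n / expected_n ∈ [0, 1].
    """
    t0, t1 = series.span if window is None else (
        pd.Timestamp(window[0]),
        pd.Timestamp(window[1]),
    )
    if t1 < t0:
        raise ValueError("empty window")
    s0, s1 = series.span
    if t0 < s0 or t1 > s1:
        raise ValueError("window must lie within the series span")
    step = pd.Timedelta(minutes=series.step_minutes)
    expected = int((t1 - t0) / step) + 1
    d = series.data
    in_win = (d.index >= t0) & (d.index <= t1)
    valid = int((d["valid"] & in_win).sum())
    return CompletenessReport((t0, t1), expected, valid)


def saturation_vapour_pressure(T: np.ndarray | float) -> np.ndarray | float:
    """Magnus-form saturation vapour pressure over water, hPa (WMO coefficients)."""
    T = np.asarray(T, dtype=float)
    return 6.112 * np.exp(17.62 * T / (243.12 + T))


def mixing_ratio(
    T: np.ndarray | float,
    RH: np.ndarray | float,
    pressure_hPa: float = STANDARD_PRESSURE_HPA,
) -> np.ndarray | float:
    """Mixing ratio (g water vapour / kg dry air) from T (°C) and RH (%).

    MR = 622 · e / (P − e) with e = (RH/100)·e_s(T); RH is in percent.
    Raises a domain error when the vapour pressure reaches the station
    pressure (the formula's pole).
    """
    T = np.asarray(T, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if np.any((T < -40) | (T > 60)):
        raise ValueError("temperature outside the psychrometric validity range [-40, 60] °C")
    if np.any((RH < 0) | (RH > 100)):
        raise ValueError("RH must be within [0, 100] %")
    e = RH / 100.0 * saturation_vapour_pressure(T)
    if np.any(pressure_hPa <= e):
        raise ValueError("station pressure must exceed the vapour pressure")
    mr = 622.0 * e / (pressure_hPa - e)
    return mr if mr.ndim else float(mr)


def resample(
    series: HygroSeries,
    step_minutes: int,
    rule: str = "mean",
    min_coverage: float = 1.0,
) -> HygroSeries:
    """Aggregate to a coarser step (an integer multiple of the nominal step).

    rule="mean": block average of valid records; blocks whose valid
    coverage falls below ``min_coverage`` propagate as missing.
    rule="instantaneous": the value observed at each block-start timestamp.
    """
    if step_minutes % series.step_minutes:
        raise ValueError(
            f"target step {step_minutes} min is not a multiple of the "
            f"nominal step {series.step_minutes} min"
        )
    per_block = int(step_minutes // series.step_minutes)
    freq = pd.Timedelta(minutes=step_minutes)
    d = series.data
    masked = d[["T", "RH"]].where(d["valid"])
    if rule == "mean":
        grouped = masked.resample(freq)
        counts = grouped["T"].count()
        agg = grouped.mean()
        low = counts < max(1, int(np.ceil(min_coverage * per_block)))
        agg.loc[low, ["T", "RH"]] = np.nan
    elif rule == "instantaneous":
        agg = masked.resample(freq).first()
    else:
        raise ValueError(f"unknown resampling rule {rule!r}")
    agg["valid"] = agg["T"].notna() & agg["RH"].notna()
    return HygroSeries(series.probe_id, agg, float(step_minutes), series.meta)
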