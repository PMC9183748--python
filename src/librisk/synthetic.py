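"""Synthetic hygrothermal, colorimetric and illuminance data generators.

The monitoring data the analysis was designed for (multi-probe indoor T/RH
at a 15-min step over full years, plus an outdoor reference) are not
publicly deposited, so every stage of the pipeline is exercised on
synthetic campaigns with the same statistical structure: a Mediterranean
outdoor climate (annual + diurnal cycles with AR(1) weather noise), an
indoor environment that tracks it through a first-order lag (massive,
naturally ventilated repository), warmer than outdoors and with markedly
damped RH variability, with indoor RH medians in the 40–50 % band.

Generators are pure functions of (parameters, seed): the same scenario and
seed regenerate bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ingest import HygroSeries, SensorMeta
from .photo import ColorMeasurement

__all__ = [
    "ClimateScenario",
    "generate_climate",
    "generate_outdoor",
    "generate_vertical_pair",
    "generate_colour_series",
    "generate_illuminance",
]


@dataclass
class ClimateScenario:
    """Parameter set for a synthetic monitoring campaign.

    Outdoor temperature is an annual sinusoid (coldest around mid-January)
    plus a diurnal cycle and AR(1) noise; outdoor RH is anti-correlated
    with the diurnal temperature and spans roughly 20–100 %. Indoor series
    are first-order lags of the outdoor ones (time constants ``tau_T_days``,
    ``tau_RH_days``) with an offset, a damped RH excursion around the
    ``rh_in_target`` median, an indoor diurnal term and AR(1) noise.

    The default noise scales target short-term residual spreads of about
    ±1 °C (ΔT₂₄ₕ) and ±5 % (ΔRH₃₀d) — the quiet, densely-shelved regime;
    :meth:`preset` offers a "ventilated" variant (≈ ±2 °C / ±10 %).
    """

    # outdoor climate
    t_mean_out: float = 15.5
    t_amp_annual: float = 8.5
    t_amp_diurnal_out: float = 4.0
    coldest_doy: int = 15
    rh_mean_out: float = 70.0
    rh_amp_annual: float = 8.0
    rh_amp_diurnal_out: float = 12.0
    rh_noise_sd_out: float = 10.0
    t_noise_sd_out: float = 1.2
    # indoor transfer
    tau_T_days: float = 5.0
    tau_RH_days: float = 15.0
    t_offset_in: float = 3.0
    rh_in_target: float = 45.0
    rh_attenuation: float = 0.35
    t_amp_diurnal_in: float = 0.9
    t_noise_sd_in: float = 0.55
    rh_noise_sd_in: float = 3.4
    ar1_phi: float = 0.97
    # campaign layout
    n_levels: int = 3
    level_dz: float = 3.5
    t_level_offset: float = 0.3
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_T_days <= 0 or self.tau_RH_days <= 0:
            raise ValueError("lag time constants must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def preset(cls, name: str, **overrides) -> "ClimateScenario":
        """Named presets: "shelved" (±1 °C/±5 %) and "ventilated" (±2 °C/±10 %)."""
        if name == "shelved":
            params: dict = {}
        elif name == "ventilated":
            params = {
                "t_amp_diurnal_in": 1.8,
                "t_noise_sd_in": 1.1,
                "rh_noise_sd_in": 6.8,
                "rh_attenuation": 0.5,
            }
        else:
            raise ValueError(f"unknown preset {name!r}")
        params.update(overrides)
        return cls(**params)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _lag_filter(x: np.ndarray, dt_days: float, tau_days: float) -> np.ndarray:
    """Exact discrete first-order lag (piecewise-constant input)."""
    alpha = 1.0 - np.exp(-dt_days / tau_days)
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, len(x)):
        y[i] = y[i - 1] + alpha * (x[i] - y[i - 1])
    return y


def _time_axes(start: str, span_days: float, step_minutes: float,
               warmup_days: float):
    step = pd.Timedelta(minutes=step_minutes)
    t0 = pd.Timestamp(start) - pd.Timedelta(days=warmup_days)
    n = int(round((span_days + warmup_days) * 24 * 60 / step_minutes)) + 1
    idx = pd.date_range(t0, periods=n, freq=step)
    doy = idx.dayofyear.to_numpy() + idx.hour.to_numpy() / 24.0
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    return idx, doy, hour


def _outdoor_fields(sc: ClimateScenario, doy, hour, rng,
                    noise: bool = True, diurnal: bool = True):
    annual = -np.cos(2 * np.pi * (doy - sc.coldest_doy) / 365.25)
    diur = -np.cos(2 * np.pi * (hour - 14.0) / 24.0)  # warmest mid-afternoon
    T = sc.t_mean_out + sc.t_amp_annual * annual
    RH = sc.rh_mean_out - sc.rh_amp_annual * annual
    if diurnal:
        T = T + sc.t_amp_diurnal_out * diur
        RH = RH - sc.rh_amp_diurnal_out * diur
    if noise:
        T = T + _ar1(rng, len(doy), sc.ar1_phi, sc.t_noise_sd_out)
        RH = RH + _ar1(rng, len(doy), sc.ar1_phi, sc.rh_noise_sd_out)
    return T, np.clip(RH, 2.0, 100.0)


def generate_outdoor(
    scenario: ClimateScenario,
    start: str = "2019-08-01",
    span_days: float = 365.0,
    step_minutes: float = 60.0,
) -> HygroSeries:
    """The outdoor reference station series for a scenario."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 99]))
    idx, doy, hour = _time_axes(start, span_days, step_minutes, 0.0)
    T, RH = _outdoor_fields(scenario, doy, hour, rng)
    df = pd.DataFrame({"T": T, "RH": RH}, index=idx)
    return HygroSeries("outdoor", df, step_minutes)


def generate_climate(
    scenario: ClimateScenario,
    start: str = "2019-08-01",
    span_days: float = 365.0,
    step_minutes: float = 15.0,
    noise: bool = True,
    diurnal: bool = True,
    warmup_days: float = 60.0,
) -> tuple[dict[str, HygroSeries], HygroSeries]:
    """Generate the indoor probe set and its outdoor reference.

    Indoor series are lag-filtered outdoor fields plus offsets, an indoor
    diurnal term and AR(1) noise; a warm-up interval before ``start`` is
    simulated and discarded so the lag filter has settled. With ``noise``
    and ``diurnal`` off the indoor temperature is the analytic first-order
    response to the outdoor sinusoid (gain 1/√(1+(ωτ)²), phase arctan(ωτ)).
    ``gap_fraction`` removes records at random, propagating into the
    Completeness Index downstream.
    """
    sq = np.random.SeedSequence([scenario.seed, 7])
    children = sq.spawn(scenario.n_levels + 2)
    idx, doy, hour = _time_axes(start, span_days, step_minutes, warmup_days)
    dt_days = step_minutes / (24 * 60.0)
    rng_out = np.random.default_rng(children[0])
    T_out, RH_out = _outdoor_fields(scenario, doy, hour, rng_out,
                                    noise=noise, diurnal=diurnal)
    keep = idx >= pd.Timestamp(start)
    diur = -np.cos(2 * np.pi * (hour - 14.0) / 24.0)

    probes: dict[str, HygroSeries] = {}
    for lev in range(scenario.n_levels):
        rng = np.random.default_rng(children[lev + 1])
        T_base = _lag_filter(T_out, dt_days, scenario.tau_T_days)
        T_in = T_base + scenario.t_offset_in + scenario.t_level_offset * lev
        RH_lag = _lag_filter(RH_out, dt_days, scenario.tau_RH_days)
        RH_in = scenario.rh_in_target + scenario.rh_attenuation * (
            RH_lag - scenario.rh_mean_out
        )
        if diurnal:
            T_in = T_in + scenario.t_amp_diurnal_in * diur
        if noise:
            T_in = T_in + _ar1(rng, len(idx), scenario.ar1_phi, scenario.t_noise_sd_in)
            RH_in = RH_in + _ar1(rng, len(idx), scenario.ar1_phi, scenario.rh_noise_sd_in)
        df = pd.DataFrame(
            {"T": T_in[keep], "RH": np.clip(RH_in, 2.0, 100.0)[keep]},
            index=idx[keep],
        )
        if scenario.gap_fraction > 0:
            rng_gap = np.random.default_rng(children[-1].spawn(scenario.n_levels)[lev])
            k = int(round(scenario.gap_fraction * len(df)))
            drop = rng_gap.choice(len(df), size=k, replace=False)
            df = df.drop(df.index[drop])
        pid = f"RHT{lev + 1}"
        probes[pid] = HygroSeries(
            pid, df, step_minutes,
            SensorMeta(pid, height_above_floor=1.8, level=lev),
        )
    out_df = pd.DataFrame({"T": T_out[keep], "RH": RH_out[keep]}, index=idx[keep])
    outdoor = HygroSeries("outdoor", out_df, step_minutes)
    return probes, outdoor


def generate_vertical_pair(
    scenario: ClimateScenario,
    regime: str,
    margin: float = 0.5,
    dz: float = 10.0,
    start: str = "2020-01-01",
    span_days: float = 30.0,
    step_minutes: float = 60.0,
) -> tuple[HygroSeries, HygroSeries]:
    """Aligned (upper, lower) temperature pair for a stability regime.

    ``winter_unstable`` makes the ceiling cooler than the mid level by
    ``margin`` °C (heat loss through a poorly insulated roof);
    ``summer_stable`` the reverse (heat accumulation aloft). With
    margin 0 the pair is isothermal (neutral within tolerance).
    """
    if regime not in ("winter_unstable", "summer_stable"):
        raise ValueError(f"unknown regime {regime!r}")
    probes, _ = generate_climate(
        scenario, start=start, span_days=span_days, step_minutes=step_minutes,
        noise=False, diurnal=True, warmup_days=10.0,
    )
    lower = probes["RHT1"]
    sign = -1.0 if regime == "winter_unstable" else 1.0
    upper_df = lower.data.copy()
    upper_df["T"] = upper_df["T"] + sign * margin
    upper = HygroSeries("ceiling", upper_df, step_minutes)
    return upper, lower


def generate_colour_series(
    E_inf: float,
    t_s: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "target",
    baseline=(75.0, -18.0, 12.0),
) -> list[ColorMeasurement]:
    """Colorimetric visit sequence following the saturation kinetics.

    ΔE*(t) = E_∞·t/(t_s + t) plus Gaussian noise (the t = 0 baseline is
    noise-free), mapped into CIELAB along a fixed fading direction from the
    chosen baseline so that the Euclidean distance to the baseline equals
    the generated ΔE*.
    """
    if E_inf < 0 or t_s <= 0:
        raise ValueError("require E_inf ≥ 0 and t_s > 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    de = E_inf * t / (t_s + t)
    if noise_sd > 0:
        de = de + np.where(t > 0, rng.normal(0, noise_sd, t.size), 0.0)
    de = np.clip(de, 0.0, None)
    direction = np.array([-0.40, 0.50, 0.768])
    direction /= np.linalg.norm(direction)
    L0, a0, b0 = baseline
    out = []
    for ti, dei in zip(t, de):
        lab = np.array([L0, a0, b0]) + dei * direction
        out.append(
            ColorMeasurement(sample_id, float(ti), float(lab[0]), float(lab[1]),
                             float(lab[2]), n_replicates=9)
        )
    return out


def generate_illuminance(
    days: int = 7,
    step_minutes: float = 10.0,
    peak_lx: float = 45_000.0,
    ceiling_lx: float = 32_000.0,
    seed: int = 0,
    start: str = "2020-07-27",
) -> pd.Series:
    """Synthetic east-facing-window illuminance with sensor-ceiling censoring.

    A clear-sky morning-peaked diurnal profile with multiplicative weather
    noise, clipped at the logger's upper measurement limit.
    """
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start, periods=int(days * 24 * 60 / step_minutes),
                        freq=pd.Timedelta(minutes=step_minutes))
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    solar = np.clip(np.cos((hour - 9.5) / 4.5 * np.pi / 2), 0.0, None) ** 1.5
    daily = rng.uniform(0.6, 1.0, days)
    weather = daily[np.minimum((np.arange(len(idx)) * step_minutes) // (24 * 60),
                               days - 1).astype(int)]
    lx = peak_lx * solar * weather
    return pd.Series(np.minimum(lx, ceiling_lx), index=idx, name="illuminance_lx")
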