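"""Biological risk: mould-germination screening against the lowest isopleth
for mould (LIM) and an insect egg-laying dose–response for the webbing
clothes moth (Tineola bisselliella).

Fungal spores are ubiquitous; germination becomes possible when relative
humidity stays above a temperature-dependent critical value. The LIM is the
lowest T→RH curve at which mould activity is assumed possible for an
optimal (worst-case) substrate, with a hard floor at 65 % RH below which no
prolonged-exposure risk is assumed. Days are screened by their maximum T and
maximum RH taken independently — a conservative worst-case pairing.

Insect proliferation is screened with an empirical monthly egg-laying count

    e(T) = int{ 130 · exp( −( (T²/30 − 30) / 12 )² ) },

unimodal in T with its maximum of 130 eggs/month exactly at 30 °C ("int" is
truncation toward zero, a literal reading of the printed formula). The
insect Risk Index compares the eggs laid over twelve months with the
theoretical annual maximum of 1560.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IsoplethModel",
    "EggCount",
    "OPTIMAL_SUBSTRATE_LIM",
    "mould_exceedance",
    "insect_eggs",
    "insect_risk_index",
    "mould_risk_index",
]

#: RH floor (%): below this no mould risk is assumed regardless of T.
RH_MOULD_FLOOR = 65.0

#: Annual theoretical maximum egg count (130 eggs/month × 12).
MAX_ANNUAL_EGGS = 1560


@dataclass
class IsoplethModel:
    """Tabulated LIM curve: ordered (T °C → critical RH %) pairs.

    ``germination_days`` optionally tabulates spore-germination time as
    (T, RH) → days curves. The provenance tag records where the numbers come
    from and their tolerance; the shipped default is an approximate,
    synthetic transcription of the optimal-substrate diagram.
    """

    substrate_class: str
    curve: list[tuple[float, float]]
    germination_days: list[tuple[float, float, float]] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.curve:
            raise ValueError("isopleth model has an empty LIM curve")
        Ts = [t for t, _ in self.curve]
        if sorted(Ts) != Ts:
            raise ValueError("LIM curve must be ordered in temperature")
        if any(rh < RH_MOULD_FLOOR for _, rh in self.curve):
            raise ValueError(f"LIM critical RH may not fall below the {RH_MOULD_FLOOR}% floor")

    @property
    def T_span(self) -> tuple[float, float]:
        return self.curve[0][0], self.curve[-1][0]

    def critical_rh(self, T: np.ndarray | float) -> np.ndarray | float:
        """Critical RH at temperature T, linearly interpolated along the LIM."""
        Ts, RHs = zip(*self.curve)
        rh = np.interp(np.asarray(T, dtype=float), Ts, RHs)
        return rh if np.ndim(rh) else float(rh)


#: Approximate optimal-substrate LIM (synthetic transcription; values are
#: read to roughly ±2 %RH off the widely reproduced germination diagram).
OPTIMAL_SUBSTRATE_LIM = IsoplethModel(
    substrate_class="optimal",
    curve=[
        (0.0, 96.0), (5.0, 88.0), (10.0, 82.0), (15.0, 78.0),
        (20.0, 75.0), (25.0, 73.0), (30.0, 72.0), (35.0, 72.0), (40.0, 73.0),
    ],
    # (T °C, RH %, days to spore germination) — coarse worst-case grid
    germination_days=[
        (25.0, 95.0, 1.0), (25.0, 90.0, 2.0), (25.0, 85.0, 4.0),
        (25.0, 80.0, 8.0), (25.0, 75.0, 16.0),
        (10.0, 95.0, 4.0), (10.0, 90.0, 8.0), (10.0, 85.0, 16.0), (10.0, 80.0, 32.0),
    ],
    provenance=(
        "approximate transcription of the optimal-substrate lowest isopleth "
        "for spore germination (±2 %RH); synthetic stand-in, editable"
    ),
)


def _germination_days(model: IsoplethModel, T: float, RH: float) -> float | None:
    """Nearest-neighbour lookup in the (coarse) germination-time table."""
    if not model.germination_days:
        return None
    pts = np.array([(t, r) for t, r, _ in model.germination_days])
    days = np.array([d for _, _, d in model.germination_days])
    # scale RH distance down: the time isopleths are much denser in RH
    dist = ((pts[:, 0] - T) / 10.0) ** 2 + ((pts[:, 1] - RH) / 5.0) ** 2
    return float(days[int(np.argmin(dist))])


def mould_exceedance(
    daily_max_T: pd.Series,
    daily_max_RH: pd.Series,
    isopleths: IsoplethModel = OPTIMAL_SUBSTRATE_LIM,
) -> pd.DataFrame:
    """Per-day mould-germination screening against the LIM.

    A day is flagged when its maximum RH exceeds the LIM critical RH
    interpolated at its maximum T (maxima taken independently). Days whose
    temperature falls outside the curve's span are not flagged and a
    warning is issued. Flagged days carry a germination-time estimate when
    the model tabulates one.
    """
    import warnings

    idx = daily_max_T.index.intersection(daily_max_RH.index)
    T = daily_max_T.reindex(idx)
    RH = daily_max_RH.reindex(idx)
    lo, hi = isopleths.T_span
    out_of_span = (T < lo) | (T > hi)
    if bool(out_of_span.any()):
        warnings.warn(
            f"{int(out_of_span.sum())} day(s) outside the LIM temperature span "
            f"[{lo}, {hi}] °C treated as no-risk",
            stacklevel=2,
        )
    crit = pd.Series(isopleths.critical_rh(T.to_numpy()), index=idx)
    flagged = RH.notna() & T.notna() & ~out_of_span & (RH > crit)
    germ = [
        _germination_days(isopleths, float(t), float(rh)) if fl else None
        for t, rh, fl in zip(T, RH, flagged)
    ]
    return pd.DataFrame(
        {
            "T_max": T,
            "RH_max": RH,
            "critical_RH": crit,
            "flagged": flagged,
            "germination_days": germ,
        }
    )


def insect_eggs(T: np.ndarray | float) -> np.ndarray | int:
    """Monthly egg count e(T) of the webbing clothes moth at mean temperature T.

    e = int{130·exp(−((T²/30 − 30)/12)²)}; truncation toward zero, so e is
    an integer in [0, 130] with the maximum attained exactly at 30 °C.
    """
    T = np.asarray(T, dtype=float)
    e = np.trunc(130.0 * np.exp(-(((T**2 / 30.0) - 30.0) / 12.0) ** 2)).astype(int)
    return e if e.ndim else int(e)


def insect_risk_index(monthly_T_means: "pd.Series | np.ndarray") -> float:
    """Insect Risk Index: eggs laid over 12 months vs the 1560 annual maximum.

    RI = 100 · Σ e(Tᵢ) / 1560, order-invariant; requires exactly twelve
    monthly mean temperatures with none missing.
    """
    t = np.asarray(pd.Series(monthly_T_means), dtype=float)
    if t.size != 12 or np.any(~np.isfinite(t)):
        raise ValueError("insect risk index requires 12 non-missing monthly T means")
    return 100.0 * float(np.sum(insect_eggs(t))) / MAX_ANNUAL_EGGS


def mould_risk_index(flags: pd.Series | pd.DataFrame) -> float:
    """Yearly percent of days flagged by the mould screening."""
    if isinstance(flags, pd.DataFrame):
        flags = flags["flagged"]
    if len(flags) == 0:
        raise ValueError("no screened days")
    return 100.0 * float(flags.mean())


@dataclass
class EggCount:
    """Monthly egg-laying record."""

    month: int
    T_mean: float
    eggs: int

    def __post_init__(self) -> None:
        if not 0 <= self.eggs <= 130:
            raise ValueError("eggs must lie in [0, 130]")


def monthly_egg_table(monthly_T_means: pd.Series) -> list[EggCount]:
    """Per-month egg counts from monthly mean temperatures."""
    return [
        EggCount(month=int(getattr(ts, "month", i + 1)), T_mean=float(t),
                 eggs=int(insect_eggs(float(t))))
        for i, (ts, t) in enumerate(monthly_T_means.items())
    ]
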