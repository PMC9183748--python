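"""Chemical risk: cellulose-hydrolysis kinetics, expected lifetime and the
time-weighted expected lifetime (TWEL).

Cellulose chains scission by acid-catalysed hydrolysis at a rate k(pH, T, RH)
per year. Under Ekenstam kinetics 1/DP(t) − 1/DP0 = k·t, so the expected
lifetime — the years until the degree of polymerisation falls from DP0 to
the critical value DP_crit below which paper is unfit for handling — is

    EL = (1/DP_crit − 1/DP0) / k.

Climate varies, so EL is evaluated per observation from the response-time
smoothed climate (T₂₄ₕ, RH₃₀d) and aggregated as the harmonic mean

    TWEL = n / Σᵢ ELᵢ⁻¹,

which is dominated by the smallest ELᵢ — the worst conditions of the window.
The chemical Risk Index is the percentage of time EL falls below a planning
horizon (500 years by default).

The dose–response coefficient set shipped here is a synthetic calibration in
the standard published functional form (Arrhenius temperature term, log-linear
acidity and humidity terms); see :data:`DEFAULT_DOSE_RESPONSE` for its
provenance tag. Alternative damage functions plug in through
:class:`DegradationModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "PaperType",
    "DegradationModel",
    "TWELResult",
    "PAPER_TYPES",
    "DEFAULT_DOSE_RESPONSE",
    "degradation_rate",
    "expected_lifetime",
    "twel",
    "seasonal_twel",
    "isochrone_grid",
    "chemical_risk_index",
]

R_GAS = 8.314462618  # J mol⁻¹ K⁻¹

#: Default critical degree of polymerisation (convention of the
#: damage-function literature; EL is meaningless without it, so it is
#: configurable per paper type and echoed in all outputs).
DP_CRIT_DEFAULT = 300.0

#: Default chemical planning horizon, years.
HORIZON_YEARS = 500.0


@dataclass(frozen=True)
class PaperType:
    """A paper class parameterising the chemical channel.

    ``pH`` is the operationally defined acidity of the paper (cold-extract
    surrogate, not a true solution pH); ``DP0`` the initial and ``DP_crit``
    the critical degree of polymerisation.
    """

    name: str
    pH: float
    DP0: float
    DP_crit: float = DP_CRIT_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.pH < 14:
            raise ValueError("pH must lie in (0, 14)")
        if not self.DP0 > self.DP_crit > 0:
            raise ValueError("require DP0 > DP_crit > 0")


#: Built-in paper classes (SurveNIR-style averages for the three types).
PAPER_TYPES: dict[str, PaperType] = {
    "rag": PaperType("rag", pH=6.4, DP0=1481.2),
    "acidic": PaperType("acidic", pH=5.2, DP0=826.3),
    "contemporary": PaperType("contemporary", pH=7.6, DP0=1526.2),
}


@dataclass(frozen=True)
class DegradationModel:
    """Named coefficient set for the hydrolysis rate k(pH, T, RH), per year.

    ln k = lnA + b_pH·pH + b_RH·RH[%] − Ea/(R·T[K])

    Monotonicity over the validity domain: increasing in T (Arrhenius,
    Ea > 0), decreasing in pH (b_pH < 0), increasing in RH (b_RH > 0).
    """

    name: str
    lnA: float
    b_pH: float
    b_RH: float
    Ea: float  # J/mol
    provenance: str
    T_domain: tuple[float, float] = (0.0, 40.0)   # °C
    RH_domain: tuple[float, float] = (20.0, 80.0)  # %
    pH_domain: tuple[float, float] = (4.0, 9.0)


#: Synthetic calibration, v1: Ea = 119 kJ/mol (canonical acid-catalysed
#: cellulose hydrolysis); acidity slope −0.244 per pH unit; humidity slope
#: +0.035 per %RH; pre-exponential anchored so acidic paper (pH 5.2,
#: DP0 826.3, DP_crit 300) at 20 °C / 45 % RH has EL ≈ 300 years.
DEFAULT_DOSE_RESPONSE = DegradationModel(
    name="cellulose-hydrolysis-synthetic-v1",
    lnA=36.66,
    b_pH=-0.244,
    b_RH=0.035,
    Ea=119_000.0,
    provenance=(
        "synthetic calibration in the standard dose-response functional form; "
        "not a transcription of any published coefficient table"
    ),
)


def _check_domain(model: DegradationModel, pH, T, RH) -> None:
    def outside(x, lo, hi):
        x = np.asarray(x, dtype=float)
        return bool(np.any((x < lo) | (x > hi)))

    if outside(T, *model.T_domain) or outside(RH, *model.RH_domain) or outside(
        pH, *model.pH_domain
    ):
        warnings.warn(
            f"inputs outside the stated validity domain of model {model.name!r}; "
            "extrapolated rates are indicative only",
            stacklevel=3,
        )


def degradation_rate(
    model: DegradationModel,
    pH: float,
    T: np.ndarray | float,
    RH: np.ndarray | float,
) -> np.ndarray | float:
    """Hydrolysis rate k (year⁻¹) at the given acidity and climate."""
    for attr in ("lnA", "b_pH", "b_RH", "Ea"):
        if getattr(model, attr) is None:
            raise ValueError(f"degradation model {model.name!r} is missing {attr}")
    _check_domain(model, pH, T, RH)
    T_K = np.asarray(T, dtype=float) + 273.15
    lnk = model.lnA + model.b_pH * pH + model.b_RH * np.asarray(RH, dtype=float) \
        - model.Ea / (R_GAS * T_K)
    k = np.exp(lnk)
    return k if np.ndim(k) else float(k)


def expected_lifetime(
    model: DegradationModel,
    paper: PaperType,
    T: np.ndarray | float,
    RH: np.ndarray | float,
) -> np.ndarray | float:
    """Expected lifetime EL = (1/DP_crit − 1/DP0)/k, years."""
    if paper.DP0 <= paper.DP_crit:
        raise ValueError("DP0 must exceed DP_crit")
    k = degradation_rate(model, paper.pH, T, RH)
    el = (1.0 / paper.DP_crit - 1.0 / paper.DP0) / k
    return el if np.ndim(el) else float(el)


@dataclass
class TWELResult:
    """Harmonic-mean expected lifetime over a labelled window."""

    window_label: str
    n: int
    TWEL: float


def twel(EL_series: pd.Series | np.ndarray, window_label: str = "year") -> TWELResult:
    """Time-weighted expected lifetime: n / Σ ELᵢ⁻¹ over the window.

    ELᵢ must come from the response-time smoothed climate (T₂₄ₕ, RH₃₀d),
    one value per observation; EL is averaged harmonically — never the rate
    k first — so the result is dominated by the worst conditions.
    """
    el = np.asarray(pd.Series(EL_series).dropna(), dtype=float)
    if el.size == 0:
        raise ValueError(f"empty window {window_label!r}: no EL values")
    if np.any(el <= 0):
        raise ValueError("all EL values must be positive")
    return TWELResult(window_label, int(el.size), float(el.size / np.sum(1.0 / el)))


#: Meteorological seasons (month → label).
SEASONS = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
           6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}


def seasonal_twel(EL_series: pd.Series, seasons: dict[int, str] | None = None) -> list[TWELResult]:
    """TWEL per meteorological season (DJF/MAM/JJA/SON by default)."""
    seasons = seasons or SEASONS
    el = EL_series.dropna()
    labels = el.index.month.map(seasons)
    out = []
    for name in dict.fromkeys(seasons.values()):
        sub = el[labels == name]
        if len(sub):
            out.append(twel(sub, window_label=name))
    return out


def isochrone_grid(
    model: DegradationModel,
    paper: PaperType,
    T_range: tuple[float, float] = (10.0, 35.0),
    RH_range: tuple[float, float] = (20.0, 80.0),
    n: int = 101,
) -> dict:
    """EL over a T×RH grid, ready for contouring at chosen year levels.

    Level curves slope downward: at higher temperature a lower humidity is
    needed for the same expected lifetime.
    """
    T = np.linspace(*T_range, n)
    RH = np.linspace(*RH_range, n)
    TT, HH = np.meshgrid(T, RH)
    EL = expected_lifetime(model, paper, TT, HH)
    return {"T": T, "RH": RH, "EL": EL}


def chemical_risk_index(EL_series: pd.Series | np.ndarray,
                        horizon: float = HORIZON_YEARS) -> float:
    """Percent of time the expected lifetime falls below the horizon."""
    el = np.asarray(pd.Series(EL_series).dropna(), dtype=float)
    if el.size == 0:
        raise ValueError("no defined EL values")
    return 100.0 * float(np.mean(el < horizon))
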