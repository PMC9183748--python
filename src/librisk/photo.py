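"""Photodeterioration: CIELAB colour differences, discolouration kinetics
and luminous-exposure budgeting.

Colour change is quantified by ΔE*, the Euclidean distance between two
points in CIELAB space (the printed definition; CIEDE2000 is available as
an alternative mode). A ΔE* of about 6 is treated as the perceptible,
non-acceptable change from the original colour. The cumulative change of an
exposed surface follows a saturating hyperbola

    ΔE*(t) = E_∞ · t / (t_s + t),

where E_∞ is the asymptotic colour difference and t_s the time at which
half of it has developed; the curve passes through (0, 0) by construction.
Luminous exposure is the time-integral of illuminance; heritage guidance
caps it annually by light-sensitivity class (0.6 Mlx·h/y for low-sensitivity
materials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ColorMeasurement",
    "DiscolourationFit",
    "delta_e",
    "fit_discolouration",
    "exposure_budget",
]

#: Perceptible-and-non-acceptable ΔE* threshold.
DELTA_E_THRESHOLD = 6.0

#: Annual luminous-exposure limit for low-sensitivity materials, Mlx·h.
ANNUAL_EXPOSURE_LIMIT_MLXH = 0.6


@dataclass
class ColorMeasurement:
    """Averaged CIELAB reading for one sample at one visit.

    ``t`` is months since baseline. ``n_replicates``/``spread`` record the
    3-point × 3-repeat averaging protocol (spread = half maximum spread
    among replicates, when available).
    """

    sample_id: str
    t: float
    L: float
    a: float
    b: float
    n_replicates: int = 1
    spread: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError("L* must lie in [0, 100]")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be ≥ 1")

    @property
    def lab(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


def delta_e(
    reference: ColorMeasurement,
    current: ColorMeasurement,
    mode: str = "euclidean",
) -> float:
    """Colour difference ΔE* between two CIELAB measurements.

    ``mode="euclidean"`` (default) is √(ΔL² + Δa² + Δb²) — a metric on
    CIELAB space. ``mode="ciede2000"`` delegates to the CIEDE2000 formula.
    """
    if mode == "euclidean":
        return float(np.linalg.norm(current.lab - reference.lab))
    if mode == "ciede2000":
        from skimage.color import deltaE_ciede2000

        return float(deltaE_ciede2000(reference.lab, current.lab))
    raise ValueError(f"unknown ΔE* mode {mode!r}")


@dataclass
class DiscolourationFit:
    """Fitted saturation kinetics: E_inf (asymptote) and t_s (half time)."""

    E_inf: float
    t_s: float
    residuals: np.ndarray
    rmse: float

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        y = self.E_inf * t / (self.t_s + t)
        return y if y.ndim else float(y)


def _model(t, E_inf, t_s):
    return E_inf * t / (t_s + t)


def fit_discolouration(times: np.ndarray, delta_e_values: np.ndarray) -> DiscolourationFit:
    """Nonlinear least squares of ΔE*(t) = E_∞·t/(t_s + t).

    Initialisation: E_∞ at the largest observed ΔE*, t_s at the median
    positive time; both parameters bounded positive. On noiseless model
    data the fit is exact (zero residual); by construction the fitted curve
    passes through the origin and reaches E_∞/2 at t = t_s.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(delta_e_values, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points to fit the saturation curve")
    if np.any(t < 0) or not np.any(t > 0):
        raise ValueError("times must be ≥ 0 with at least one positive")
    if np.allclose(y, 0):
        raise ValueError("degenerate fit: all ΔE* values are zero")
    p0 = (float(max(y.max(), 1e-6)), float(np.median(t[t > 0])))
    popt, _ = curve_fit(
        _model, t, y, p0=p0, bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20000
    )
    resid = y - _model(t, *popt)
    return DiscolourationFit(
        E_inf=float(popt[0]),
        t_s=float(popt[1]),
        residuals=resid,
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def exposure_budget(
    illuminance: pd.Series,
    annual_limit_Mlxh: float = ANNUAL_EXPOSURE_LIMIT_MLXH,
    sensor_ceiling_lx: float | None = None,
) -> dict:
    """Cumulative luminous exposure (Mlx·h) and limit exceedance.

    Trapezoidal integral of illuminance (lx) over time. Readings at the
    sensor ceiling are integrated at the ceiling value and flagged: the
    total is then a lower bound. Negative illuminance is a data error.
    """
    x = illuminance.dropna()
    if (x < 0).any():
        raise ValueError("negative illuminance reading")
    if len(x) < 2:
        raise ValueError("need at least two readings to integrate")
    idx = x.index
    if not idx.is_monotonic_increasing:
        raise ValueError("illuminance timestamps must be increasing")
    hours = (idx - idx[0]).total_seconds() / 3600.0
    total_lxh = float(np.trapezoid(x.to_numpy(), hours))
    censored = bool((x >= sensor_ceiling_lx).any()) if sensor_ceiling_lx else False
    total = total_lxh / 1e6
    return {
        "exposure_Mlxh": total,
        "exceeds_annual_limit": total > annual_limit_Mlxh,
        "annual_limit_Mlxh": annual_limit_Mlxh,
        "censored_lower_bound": censored,
    }
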