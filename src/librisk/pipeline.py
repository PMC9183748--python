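"""End-to-end orchestration: ingest → characterise → four risk channels →
profile, per collection, on a common yearly window."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biological, chemical, climate, mechanical
from .biological import OPTIMAL_SUBSTRATE_LIM, IsoplethModel
from .config import PipelineConfig
from .ingest import HygroSeries, completeness_index
from .report import RiskProfile, assemble_risk_profile

log = logging.getLogger("librisk")

__all__ = ["ChannelOutputs", "run_channels", "run_pipeline"]


@dataclass
class ChannelOutputs:
    """All per-collection intermediate products, for reporting and audit."""

    probe_id: str
    window_label: str
    CoI: float
    smoothed: climate.SmoothedSeries
    band: mechanical.ToleranceBand
    mechanical_RI: float
    EL: dict[str, pd.Series]
    twel_year: dict[str, chemical.TWELResult]
    twel_seasonal: dict[str, list[chemical.TWELResult]]
    chemical_RI: dict[str, float]
    mould_table: pd.DataFrame
    mould_RI: float
    egg_table: pd.DataFrame
    insect_RI: float


def _window_label(series: HygroSeries) -> str:
    t0, t1 = series.span
    return f"{t0.date()}..{t1.date()}"


def run_channels(
    series: HygroSeries,
    config: PipelineConfig,
    isopleths: IsoplethModel | None = None,
    model: chemical.DegradationModel | None = None,
) -> ChannelOutputs:
    """Compute the four risk channels for one representative probe."""
    cfg = config
    label = _window_label(series)
    coi = completeness_index(series).CoI
    log.info("probe %s window %s CoI=%.3f", series.probe_id, label, coi)

    smoothed = climate.centred_moving_average(
        series,
        window_T=cfg.smoothing.window_T,
        window_RH=cfg.smoothing.window_RH,
        min_coverage=cfg.smoothing.min_coverage,
    )

    band = mechanical.historical_climate_band(
        smoothed, percentiles=cfg.mechanical.percentiles,
        relaxation=cfg.mechanical.relaxation,
    )
    mech_ri = mechanical.mechanical_risk_index(band)

    model = model or chemical.DEFAULT_DOSE_RESPONSE
    f = smoothed.frame
    ok = f["T_24h"].notna() & f["RH_30d"].notna()
    EL: dict[str, pd.Series] = {}
    twel_year: dict[str, chemical.TWELResult] = {}
    twel_seasonal: dict[str, list] = {}
    chem_ri: dict[str, float] = {}
    for name in cfg.chemical.paper_types:
        base = chemical.PAPER_TYPES[name]
        paper = chemical.PaperType(base.name, base.pH, base.DP0, cfg.chemical.DP_crit)
        el = pd.Series(np.nan, index=f.index)
        el[ok] = chemical.expected_lifetime(
            model, paper, f.loc[ok, "T_24h"].to_numpy(), f.loc[ok, "RH_30d"].to_numpy()
        )
        EL[name] = el
        twel_year[name] = chemical.twel(el, window_label=label)
        twel_seasonal[name] = chemical.seasonal_twel(el)
        chem_ri[name] = chemical.chemical_risk_index(el, cfg.chemical.horizon_years)

    valid = series.valid_frame()
    daily_max_T = valid["T"].resample("1D").max()
    daily_max_RH = valid["RH"].resample("1D").max()
    mould_table = biological.mould_exceedance(
        daily_max_T.dropna(), daily_max_RH.dropna(), isopleths or OPTIMAL_SUBSTRATE_LIM
    )
    mould_ri = biological.mould_risk_index(mould_table)

    monthly_T = valid["T"].groupby(valid.index.month).mean()
    if len(monthly_T) != 12:
        raise ValueError(
            f"insect risk index needs all 12 calendar months; probe "
            f"{series.probe_id!r} covers {len(monthly_T)}"
        )
    insect_ri = biological.insect_risk_index(monthly_T.to_numpy())
    egg_table = pd.DataFrame(
        {
            "T_mean": monthly_T,
            "eggs": biological.insect_eggs(monthly_T.to_numpy()),
        }
    )
    egg_table.index.name = "month"

    return ChannelOutputs(
        probe_id=series.probe_id,
        window_label=label,
        CoI=coi,
        smoothed=smoothed,
        band=band,
        mechanical_RI=mech_ri,
        EL=EL,
        twel_year=twel_year,
        twel_seasonal=twel_seasonal,
        chemical_RI=chem_ri,
        mould_table=mould_table,
        mould_RI=mould_ri,
        egg_table=egg_table,
        insect_RI=insect_ri,
    )


def run_pipeline(
    indoor: dict[str, HygroSeries],
    config: PipelineConfig,
    outdoor: HygroSeries | None = None,
    collections: dict[str, str] | None = None,
    isopleths: IsoplethModel | None = None,
) -> dict:
    """Run the whole assessment.

    ``collections`` maps a collection label to its representative probe id
    (default: every probe is its own collection). Returns profiles, channel
    outputs and — when an outdoor series is supplied — the indoor–outdoor
    monthly comparison; without one, indoor-only channels still run and the
    comparison is skipped with a warning.
    """
    collections = collections or {pid: pid for pid in indoor}
    profiles: list[RiskProfile] = []
    channels: dict[str, ChannelOutputs] = {}
    comparisons: dict[str, dict] = {}
    for label, pid in collections.items():
        if pid not in indoor:
            raise KeyError(f"collection {label!r} references unknown probe {pid!r}")
        ch = run_channels(indoor[pid], config, isopleths=isopleths)
        channels[label] = ch
        profiles.append(
            assemble_risk_profile(
                label,
                mechanical=(ch.window_label, ch.mechanical_RI),
                chemical=(ch.window_label, ch.chemical_RI),
                mould=(ch.window_label, ch.mould_RI),
                insect=(ch.window_label, ch.insect_RI),
                provenance={
                    "probe": pid,
                    "CoI": ch.CoI,
                    "DP_crit": config.chemical.DP_crit,
                    "horizon_years": config.chemical.horizon_years,
                    "config_seed": config.seed,
                },
            )
        )
        if outdoor is not None:
            try:
                cmp_ = climate.monthly_indoor_outdoor(indoor[pid], outdoor, "T")
                comparisons[label] = {
                    "slope": cmp_["slope"],
                    "intercept": cmp_["intercept"],
                    "r_squared": cmp_["r_squared"],
                }
            except ValueError as exc:
                log.warning("indoor-outdoor comparison skipped for %s: %s", label, exc)
        else:
            log.warning("no outdoor series: indoor-outdoor comparison skipped")
    return {"profiles": profiles, "channels": channels, "comparisons": comparisons}
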