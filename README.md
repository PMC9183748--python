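# librisk

Climate-induced conservation-risk assessment for paper collections in
library and archival repositories.

Libraries keep centuries of paper in environments they can only partly
control. From nothing more than logged temperature and relative humidity
(plus optional colorimetric and illuminance measurements), `librisk`
quantifies the four deterioration channels that matter for paper and
presents them as a yearly **Risk Index** profile, each channel in percent
of time:

- **mechanical** — RH excursions outside the EN 15757 "historical climate"
  tolerance band: offsets at the 7th/93rd percentiles of the short-term
  fluctuations ΔRH₃₀d around the 30-day seasonal level, relaxed per limit
  to ±10 % when fluctuations are small;
- **chemical** — cellulose hydrolysis under Ekenstam kinetics: expected
  lifetime EL = (1/DP_crit − 1/DP₀)/k(pH, T, RH), aggregated over the year
  as the time-weighted expected lifetime TWEL = n/Σ ELᵢ⁻¹ (a harmonic mean,
  dominated by the worst conditions) and reported as the percent of time
  EL < 500 years;
- **biological** — mould-germination screening of daily maxima against the
  lowest isopleth for mould (optimal substrate, 65 % RH floor), and webbing
  clothes moth egg-laying e(T) = int{130·exp(−(((T²/30)−30)/12)²)} against
  the 1560-egg annual maximum;
- **photodeterioration** — CIELAB colour difference ΔE* (perceptibility
  threshold 6), saturation kinetics ΔE*(t) = E_∞·t/(t_s+t), and luminous
  exposure budgeting against 0.6 Mlx·h/year.

All risk computations run on response-time-smoothed climate (24-h moving
average for T, 30-day for RH), because shelved books feel the smoothed
climate, not the raw sensor record. A deterministic synthetic-campaign
generator stands in for monitoring data, so the whole pipeline is testable
end to end without any proprietary logger files. See `docs/methods.md` for
models, defaults and limitations.

## Worked example

The `analysis/` directory is a numbered walk-through on the synthetic demo
campaign (a quiet shelved area with three probe levels, "Ancient", and a
ventilated area, "Modern", one year-plus of hourly data):

```
python analysis/01_simulate_campaign.py
python analysis/02_qc_characterise.py
...
python analysis/07_risk_profile.py
```

Step 07 prints the assembled profiles (abridged):

```
Ancient (2019-08-01..2020-08-15):
  mechanical                      0.0 %
  chemical (rag)                 44.1 %
  chemical (acidic)              58.0 %
  chemical (contemporary)        37.5 %
  mould                           0.0 %
  insect                         28.1 %
Modern (2019-08-01..2020-08-15):
  mechanical                     13.5 %
  chemical (acidic)              56.7 %
  ...
```

Reading: RH fluctuations in the shelved area never leave the historical-
climate band (mechanical 0 %), while the ventilated area keeps a
percentile-based limit and sits just under the 14 % cap such limits imply.
Acidic paper spends more than half the year in conditions with expected
lifetime under the 500-year planning horizon (its yearly TWEL is ≈ 245
years in the Ancient area), rag paper is at risk mainly in summer and
autumn, and contemporary paper clears the horizon on a yearly basis. Mould
never crosses the germination isopleth; moth egg-laying peaks in July.
Intermediate tables land under `results/`.

The same steps are available as a CLI for real logger exports
(`librisk simulate | qc | characterise | risk | report`); inputs are plain
delimited text with timestamp/T/RH columns.

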