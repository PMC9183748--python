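# Methods

`librisk` assesses the climate-induced deterioration risks of paper-based
collections from indoor temperature/relative-humidity monitoring. This note
records the models, the defaults and the judgement calls, so results can be
interpreted — and challenged — without reading the source.

## Input model and quality control

The pipeline's universal input is a single-probe time series of T (°C) and
RH (%) at a fixed nominal step (15 min is typical of repository campaigns;
the demo campaign uses 1 h to keep runtimes small). Physically impossible
values (RH outside [0, 100]) are flagged invalid and retained — never
clipped, never silently dropped — so the raw record stays auditable while
every analysis sees only valid rows. Data quality over a window is the
Completeness Index, CoI = valid records / expected records at the nominal
step. The literature the index comes from does not fix the weighting of
partial days; we use the plain ratio and document it as an interpretation.

The mixing ratio (g water vapour per kg dry air) uses a Magnus-form
saturation vapour pressure with WMO coefficients, e_s = 6.112·exp(17.62·T /
(243.12 + T)) hPa, and MR = 622·e/(P − e) with a configurable station
pressure (default 1013.25 hPa). This is routine psychrometrics; no claim of
novelty is attached to it.

## Response-time smoothing

Paper books equilibrate slowly, so risk is driven by the climate *they*
feel, not by raw sensor readings. Each variable is decomposed into a
centred moving average matched to the response time of shelved books —
24 h for T, 30 days for RH — and the residual short-term fluctuations
ΔT₂₄ₕ = T − T₂₄ₕ, ΔRH₃₀d = RH − RH₃₀d. The average is undefined where less
than `min_coverage` (default 0.9) of the window is valid, and the leading
and trailing half-windows are trimmed (15 days at each end for RH₃₀d), not
extrapolated. The identity X = smoothed + residual holds wherever both are
defined and is property-tested.

## Vertical stability

The vertical temperature gradient between two probe levels, rescaled to
°C per 10 m, is compared with the dry adiabatic reference of −0.1 °C/10 m:
air with temperature falling faster than adiabatic with height is buoyantly
unstable and rises, carrying dust and spores to the ceiling. Convention
adopted here: g = (T_upper − T_lower)/Δz·10; **unstable** when
g < −0.1 − tol; **neutral** when |g| ≤ tol (indistinguishable from no
layering at instrument resolution, default tol = 0.05 °C/10 m, of the order
of the ±0.3 °C probe uncertainty over 10 m); **stable** otherwise. The
neutral-band width is a configuration knob, not a measured constant — no
published width exists for this screening, and the sign conventions in the
field are inconsistent enough that we state ours explicitly.

## Mechanical risk (historical climate, EN 15757:2010)

Hygroscopic objects acclimatise to their long-term climate; mechanical
stress tracks short-term RH excursions outside it. The tolerance band is
built around RH₃₀d with offsets from the 7th/93rd percentiles of the ΔRH₃₀d
distribution, each limit independently relaxed to ±10 RH percentage points
when its percentile lies inside ±10 (percentile limits would then be
unnecessarily strict). The band is therefore the *wider* of the percentile
and ±10 offsets per limit. Quantiles use linear interpolation between order
statistics. The mechanical Risk Index is the percent of observations
outside the band; evaluated on the defining sample with percentile limits
it cannot exceed 14 % (7 % of quantile mass per tail) — an invariant the
suite asserts on twenty random synthetic years. Bands are evaluated only
where RH₃₀d is defined; trimmed edges are skipped.

## Chemical risk (hydrolysis kinetics, EL, TWEL)

Cellulose chains scission by acid-catalysed hydrolysis. Under Ekenstam
kinetics 1/DP − 1/DP₀ = k·t, the expected lifetime until the degree of
polymerisation falls to a critical value is EL = (1/DP_crit − 1/DP₀)/k.
DP_crit defaults to 300 (the convention of the damage-function literature
for "unfit for handling"), is configurable per paper type, and is echoed in
every output, because EL is meaningless without it.

The rate model is a pluggable coefficient set in the standard dose–response
functional form

    ln k = ln A + b_pH·pH + b_RH·RH[%] − E_a/(R·T[K])

The shipped default (`cellulose-hydrolysis-synthetic-v1`) is a **synthetic
calibration, not a transcription of any published coefficient table** (its
provenance tag says so): E_a = 119 kJ/mol, the canonical magnitude for
acid-catalysed cellulose hydrolysis; b_pH = −0.244 per pH unit;
b_RH = +0.035 per %RH; ln A = 36.66 anchored so that acidic paper (pH 5.2,
DP₀ 826.3) at 20 °C / 45 % RH has EL ≈ 300 years, the magnitude reported
for acidic stock in repository conditions. Monotonicities (k increasing in
T and RH, decreasing in pH) and the resulting orderings across paper
classes are asserted; absolute lifetimes from the default set are
indicative, and any externally validated coefficient set can be dropped in
through `DegradationModel`. A declared validity domain (0–40 °C, 20–80 %RH,
pH 4–9) produces warnings, not errors, outside it.

EL is evaluated **per observation from the smoothed climate** (T₂₄ₕ,
RH₃₀d) — matching the response time of books — and aggregated as the
time-weighted expected lifetime, the harmonic mean TWEL = n/Σ ELᵢ⁻¹, which
is dominated by the worst (shortest-EL) conditions; k is never averaged
first. TWEL = EL exactly under constant climate, and harmonic ≤ arithmetic
always; both are property-tested. Seasons default to meteorological
quarters (DJF/MAM/JJA/SON). The chemical Risk Index is the percent of time
EL < 500 years, the planning horizon typical of historic libraries. Light
is deliberately absent from EL, so the chemical channel is a lower bound
for light-exposed items (the photodeterioration channel covers that side).

Built-in paper classes (SurveNIR-style averages): rag pH 6.4 / DP₀ 1481.2,
acidic pH 5.2 / DP₀ 826.3, contemporary pH 7.6 / DP₀ 1526.2.

## Biological risk

**Mould.** Daily maximum T and daily maximum RH — maxima taken
independently, the conservative worst-case pairing — are screened against
the Lowest Isopleth for Mould for an optimal substrate: the T→critical-RH
curve below which spore germination is assumed impossible, floored at 65 %
RH. The shipped curve is an approximate transcription (±2 %RH) of the
widely reproduced optimal-substrate germination diagram; it is an editable
data table with a provenance tag, and the coarse germination-time table
attached to it yields order-of-magnitude day estimates only. Days outside
the curve's temperature span are treated as no-risk with a warning. The
mould Risk Index is the percent of days flagged.

**Insects.** Monthly egg-laying of the webbing clothes moth is the
empirical dose–response e(T) = int{130·exp(−(((T²/30) − 30)/12)²)}: an
integer count, unimodal with its maximum of 130 eggs/month exactly at
30 °C. "int" is truncation toward zero — the literal reading of the printed
formula — so e never exceeds the untruncated value. The insect Risk Index
compares the twelve monthly counts against the theoretical annual maximum
of 1560 eggs; all twelve months are required.

## Photodeterioration

ΔE* is the Euclidean distance in CIELAB space (the definition used for the
perceptibility threshold of 6); CIEDE2000 is available as an alternative
mode via scikit-image but is not the default, because the threshold and
the kinetics below are defined on the Euclidean form. Cumulative
discolouration follows the saturating hyperbola ΔE*(t) = E_∞·t/(t_s + t),
fitted by bounded nonlinear least squares (initialised at the largest
observed ΔE* and the median positive time; unweighted, since replicate
spreads are not reliably available). The fit is exact on noiseless model
data and passes through the origin by construction; Monte-Carlo recovery
(σ = 1, 50 replicates) keeps the median E_∞ within 5 % of truth.

Luminous exposure is the trapezoidal time-integral of illuminance,
reported in Mlx·h against the CEN/TS-style annual budget of 0.6 Mlx·h for
low-sensitivity materials. Readings at the sensor ceiling (e.g. 32 000 lx
loggers) are integrated at the ceiling value and the total flagged as a
lower bound.

## Risk Index profile

The four channels are reported side by side, each in percent of time on
the same yearly window (mould uses percent of *days*, consistent with its
daily screening; the other channels use observation fractions). Assembly is
a pure function of the channel outputs — nothing is recomputed — and a
window mismatch between channels is an error. The channels are deliberately
not combined into one scalar: they act on different materials and call for
different mitigations.

## Synthetic campaign generator

The generator emulates the structure of a Mediterranean repository
campaign: outdoor T as an annual sinusoid (mean 15.5 °C, amplitude 8.5 °C,
coldest mid-January) with a diurnal cycle and AR(1) weather noise; outdoor
RH anti-correlated with the diurnal cycle, spanning roughly 20–100 %;
indoor series obtained by first-order lag filtering (τ_T = 5 d,
τ_RH = 15 d), a +3 °C indoor offset, RH damped toward a 40–50 % median
band, plus indoor diurnal and AR(1) terms. With noise and diurnal terms
disabled the indoor temperature is the analytic first-order response to
the outdoor sinusoid (gain 1/√(1+(ωτ)²), phase lag arctan(ωτ)/ω), which
the suite checks in closed form. Default noise scales target short-term
spreads of ≈ ±1 °C (ΔT₂₄ₕ) and ≈ ±5 % (ΔRH₃₀d) — a quiet densely-shelved
area — with a "ventilated" preset at ≈ ±2 °C / ±10 %. AR(1) was chosen as
the simplest noise with the short-term persistence that ventilation events
produce. Everything is a pure function of (parameters, seed).

What the generator does **not** emulate: real sensor drift and
inter-sensor calibration offsets, occupancy-driven weekday/weekend
structure, heating-system switching, condensation microclimates near cold
surfaces, and any air-exchange physics. Passing tests therefore demonstrate
the correctness and the invariants of the *methods* under realistic
statistical structure, not site-specific conclusions about any particular
building.

## Numerical choices and degenerate inputs

- Quantiles: numpy linear interpolation between order statistics, logged in
  band metadata.
- Resampling to coarser steps requires an integer multiple of the nominal
  step; blocks below the coverage requirement propagate as missing.
- Duplicate timestamps (including DST-fold duplicates; timestamps are local
  time without DST arithmetic) are rejected as data errors.
- Empty windows, all-zero discolouration series, DP₀ ≤ DP_crit, non-positive
  lag time constants and negative illuminance are errors, not warnings.
- Problem sizes: the demo campaign and the test suite use one year-plus
  (380 d) of hourly data per probe — enough for the 30-day smoothing, the
  annual band and all twelve calendar months — which keeps the whole suite
  in the seconds-to-minutes range.

## Known limitations

- Absolute chemical lifetimes inherit the synthetic calibration of the
  default dose–response set; orderings and risk rankings are robust to it,
  absolute years are not.
- The LIM table is an approximate transcription; near-curve cases (within
  a few %RH) should not be over-interpreted.
- The ±10 relaxation interacts with mixed cases (one limit percentile, one
  relaxed); both-limit behaviour is reported per limit in the band
  metadata.
- No sensor-drift correction, no spatial interpolation between probes, no
  building-physics simulation, no pollutant term (generally negligible for
  paper), no light term inside EL.
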