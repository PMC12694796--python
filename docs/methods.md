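# Methods

## The indices

`hmrisk` scores hourly indoor-environment monitoring data against
conservation and health standards with two normalized indices. Both are
built from the same two components, computed per indicator and room:

- **HMR_env** compares the period-average of an indicator with its
  standard. For a *range* indicator with adjusted bounds `(lo, hi)`,

      HMR_env = 1 - 2 * (hi - mean) / (hi - lo),

  an affine map placing the range midpoint at 0 and the bounds at -1
  (deficit) and +1 (excess), clamped to `[-1, 1]`.

- **HMR_osc** measures day-to-day variability: the mean over all
  consecutive-day pairs and hours of `|X(day k, hour j) - X(day k+1,
  hour j)|`, normalized against the allowed daily-oscillation band
  `(osc_low, osc_high)` by the same affine map. Pairs with a missing
  value on either day are skipped, and the mean divides by the number
  of differences actually summed.

- **HMR = (HMR_env + HMR_osc) / 2**, and per-indicator scores aggregate
  by unweighted means to room averages and an overall average.

The exhibit-conservation index **HMR_E** uses the range indicators
(temperature, relative humidity, artificial light) on the signed scale
`[-1, 1]`. The human-health index **HMR_H** uses the threshold
indicators (CO2, HCHO, TVOC, PM2.5, PM10, positive and negative air
ions) on `[0, 1]` — these standards are one-sided bounds, so risk only
accrues on one side.

### Threshold scoring: semantic vs verbatim

The literature formula for the threshold mean component,
`1 - 2 * (P_mean - P_opt) / (P_max - P_opt)`, evaluates to +1 when the
mean sits *at* the threshold and falls as the mean approaches the
saturation value `P_max` — the opposite of the stated semantics that the
index should grow with the value, number and frequency of exceedances.
The package therefore defaults to a *semantic* scoring rule:

    HMR_env = clamp(alpha * E_mag + (1 - alpha) * E_freq, 0, 1)

with `E_mag` the mean's normalized exceedance of the threshold (0 at or
below the threshold, 1 at saturation), `E_freq` the fraction of
observations exceeding it, and `alpha = 0.5`. This is 0 exactly when no
observation exceeds the threshold and 1 at joint saturation, and is
monotone in both magnitude and frequency. The oscillation analogue is
`clamp((dP_mean - dP_opt) / (dP_max - dP_opt), 0, 1)` with `dP_max` the
worst observed same-hour change and `dP_opt` the safe floor
(`osc_low`); when nothing varies beyond the floor the score is 0 rather
than a division by zero. The printed normalisations remain available as
`threshold_verbatim` (clamped to `[0, 1]`) for auditability, and every
output manifest records which mode produced it.

For a *lower* threshold (negative air ions, which should stay **above**
1000 ions/cm3) the axis is mirrored: risk is the deficit below the
limit, saturating by default at 0 ions/cm3.

Range indicators have an analogous choice: `range_verbatim` (the linear
map above, default) versus `exceedance_only`, which scores 0 anywhere
inside the range and proportionally to the overshoot outside it — both
readings of the methodology are implemented and selectable.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `osc_fraction` | multiplicative widening of range bounds, `high*(1+f)`, `low*(1-f)` | 0 | the published limits apply verbatim unless a project chooses otherwise |
| `osc_low`, `osc_high` | allowed daily same-hour oscillation band, per indicator | see `data/table2_defaults.yaml` | issuing standards do not publish these; values are conservation-practice defaults, meant to be overridden |
| `saturation` (`P_max`) | value where a one-sided score saturates at 1 | 2x threshold (upper), 0 (lower) | no published value exists; a documented, overridable convention |
| `alpha` | magnitude-vs-frequency blend of the semantic score | 0.5 | equal weight; no basis to prefer either term |
| band cut points | low / moderate / high on \|score\| | 0.2, 0.6 | inferred from the published anchors (0.4 = moderate, 0.128 = low); configurable |
| display rounding | table output | 2 decimals, half away from zero | matches the precision of the published tables; internal math is full precision |

Missing hours are excluded from every count (`N` is the number of values
actually present); no imputation is performed. Cross-sensor aggregation
within a room is the unweighted per-timestamp mean over the sensors that
reported at that hour — sensors are assumed spatially balanced.

## CFU quantitation

Plate counts convert as `CFU/g = NCC * DF / VP` (dilution factor 50,
1 mL plated by default) in exact integer arithmetic. A "< 10" report is
modelled as a below-detection censor state, not a count: with DF = 50 a
single colony already implies 50 CFU/g, so "< 10" is an assay reporting
convention, preserved as a censored value with its printed limit.
"Uncountable" is right-censoring above a 300-colonies/plate ceiling (the
standard countable-range convention). All fold changes and
treated-vs-untreated contrasts propagate censoring as bounds
(`lower_bound` / `upper_bound` / `indeterminate`) rather than invented
numbers. The assay simulator draws Poisson counts with a treatment
log10-reduction effect; the estimator `log10(mean untreated count /
mean treated count)` recovers the generating reduction within
Monte-Carlo error (below-detection plates count as 0 colonies,
uncountable plates as the ceiling, so the estimate is a lower bound when
uncountable plates occur).

## Synthetic campaign

The generator produces `baseline + diurnal sinusoid + linear seasonal
drift + AR(1) noise + additive boxcar exceedance pulses`, hourly, fully
determined by a seed. AR(1) (phi = 0.8) rather than white noise because
hourly indoor readings are strongly autocorrelated; the pulse process
(Poisson arrivals, fixed magnitude and duration) independently controls
the frequency, size and number of threshold exceedances the semantic
score responds to.

The packaged demo campaign covers two exhibition rooms and all ten
indicators over 240 days (an 8-month hourly campaign). Baselines and
spreads follow the descriptive statistics reported for a monitored
museum space: T 19.9/19.4 degC with ~1.4/1.3 total sd, RH 60.8/63.9 %
with ~7/6.6 sd (persistently above the 60 % bound), CO2 493/519 ppm
with rare spikes past 1000 ppm, formaldehyde persistently above its
0.04 mg/m3 threshold, positive-ion excess and negative-ion deficit
episodes. Indicators without published spreads (AL, TVOC, PM) use
values consistent with the qualitative findings.

What the generator does **not** emulate: cross-indicator coupling
(e.g. RH-T dependence), HVAC regime switches, occupancy-driven
weekly cycles, sensor drift or calibration error. Passing tests on
synthetic data therefore demonstrate the correctness and sensitivity of
the scoring machinery, not the field accuracy of any particular risk
number.

## Numerical choices

- The oscillation sum uses `math.fsum`, so it is correctly rounded and
  independent of traversal order.
- All scores are clamped to their scale after evaluation; inputs outside
  the normalisation interval saturate rather than escape the scale.
- Degenerate configurations fail loudly (equal range bounds, saturation
  at the threshold) except the one case with a natural value: zero
  oscillation beyond the safe floor scores 0.
- Display rounding is half-away-from-zero through guard digits, so
  decimal ties that sit just below .5 in binary still round the way the
  published tables print them.
- CSV round-trips are bit-exact (`repr` on write, round-trip float
  parsing on read).

## Known limitations

- The per-indicator component values of the original campaign cannot be
  reproduced: the raw series were never deposited and several
  normalization constants (the oscillation fractions and bands, the
  threshold saturations) are unpublished. Only the aggregation
  arithmetic is verifiable against the published tables, and one
  printed cell (positive ions, second room) is inconsistent with its
  own components — treated as a typo, not emulated.
- Scores are per-indicator and additive; no interaction between
  indicators (e.g. mould risk from joint high RH and T) is modelled.
- The persistence summary is descriptive; it does not fit a growth or
  survival model to the two time points.
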