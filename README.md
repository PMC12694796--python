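# hmrisk

Heritage Microclimate Risk assessment for museum indoor environments.

Museums monitor temperature, relative humidity, light and airborne
pollutants continuously, but a wall of hourly numbers does not answer
the two questions that matter: *is this microclimate degrading the
exhibits,* and *is it safe for the people inside?* `hmrisk` condenses
hourly multi-indicator sensor campaigns into two normalized indices:

- **HMR_E** (exhibit conservation) — scored on `[-1, +1]` from the
  range-standard indicators T, RH and artificial light: 0 means optimal
  conditions, +1 excess above the acceptable range, -1 deficit below it.
- **HMR_H** (human health) — scored on `[0, 1]` from the one-sided
  threshold indicators CO2, HCHO, TVOC, PM2.5, PM10 and positive/negative
  air ions: 0 when every observation respects its threshold, growing
  with the magnitude and frequency of exceedances.

Each index blends a *mean-level* component (`HMR_env`: where the period
average sits relative to the standard) and an *oscillation* component
(`HMR_osc`: how large the day-to-day same-hour fluctuations are relative
to the allowed daily variation):

    HMR = (HMR_env + HMR_osc) / 2

with per-indicator scores averaged to room and overall values and mapped
onto a low / moderate / high risk scale. A companion module quantifies
antimicrobial-treatment efficacy on textile exhibits from plate colony
counts (`CFU/g = NCC x DF / VP`, with censoring-aware "< limit" and
"uncountable" handling), and a synthetic-data module generates full
hourly campaigns — diurnal cycles, seasonal drift, autocorrelated noise
and controllable exceedance events — so the whole pipeline is testable
without proprietary sensor data. See `docs/methods.md` for the model
details and defaults.

## Worked example

Simulate a 60-day two-room campaign, assess it against the packaged
standards, and print the summary:

```sh
hmrisk simulate --seed 7 --days 60 --out demo.csv
hmrisk assess --input demo.csv --out demo_out
hmrisk report --assessment demo_out/assessment.json
```

```
Exhibit-conservation index (HMR_E)
  EH 1-2: env=+0.198 osc=+0.297 combined=+0.247 [moderate/excess]
  EH 3: env=+0.173 osc=+0.172 combined=+0.173 [low/excess]
  overall: env=+0.186 osc=+0.234 combined=+0.210 [moderate/excess]

Human-health index (HMR_H)
  EH 1-2: env=+0.233 osc=+0.172 combined=+0.203 [moderate]
  EH 3: env=+0.198 osc=+0.187 combined=+0.193 [low]
  overall: env=+0.216 osc=+0.180 combined=+0.198 [low]
```

Reading it: the simulated rooms carry a mild *excess* conservation risk
(RH sits above its 45-60 % acceptability range and formaldehyde runs
above its 0.04 mg/m3 threshold in this campaign), while the overall
health index stays in the low band. `demo_out/` also contains
`hmr_e.csv` and `hmr_h.csv` (per-indicator component tables with room
and overall averages), `assessment.json` (full-precision scores and
risk bands) and `manifest.json` (scoring modes, input checksums —
every run is reproducible from its manifest).

The same library surface is available programmatically:

```python
from hmrisk import assess, default_standards, demo_campaign, registry

specs = registry(default_standards())
rooms = demo_campaign(seed=7, n_days=60)
result = assess(rooms, specs, "HMR_E")
print(result.overall, str(result.overall_label))
```

For the microbiology stage, `hmrisk cfu --input colonies.csv --out out/`
converts plate counts to CFU/g and writes a treated-vs-untreated
persistence table; `--simulate` generates a seeded Poisson assay with a
known log10 reduction instead.

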