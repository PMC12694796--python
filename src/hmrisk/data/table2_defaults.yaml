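# Default indicator standards for the HMR indices.
#
# Limits (low/high) follow the international standards commonly applied to
# museum indoor environments: ASHRAE ranges for temperature and relative
# humidity, the BSI illuminance range for light-sensitive exhibits, and
# ANSI/ASHRAE, EPA and WHO thresholds for the pollutant indicators.
#
# osc_low / osc_high bound the *allowed* daily same-hour oscillation used by
# the oscillation component; the issuing standards do not publish these, so
# the values below are conservative conservation-practice defaults and are
# meant to be overridden per project.  osc_fraction defaults to 0 (the bare
# published limits are used unadjusted).  saturation is the value at which
# the one-sided threshold score saturates at 1 (default 2x the threshold for
# upper thresholds; 0 for the lower-threshold ion deficit).
indicators:
  - name: T
    unit: "degC"
    mode: range
    low: 16.0
    high: 24.0
    osc_fraction: 0.0
    osc_low: 0.5
    osc_high: 2.0
    source: "ASHRAE Standard (museum/gallery class of control)"
  - name: RH
    unit: "%"
    mode: range
    low: 45.0
    high: 60.0
    osc_fraction: 0.0
    osc_low: 1.0
    osc_high: 5.0
    source: "ASHRAE Standard (museum/gallery class of control)"
  - name: AL
    unit: "lux"
    mode: range
    low: 50.0
    high: 200.0
    osc_fraction: 0.0
    osc_low: 5.0
    osc_high: 50.0
    source: "British Standards Institution"
  - name: CO2
    unit: "ppm"
    mode: upper_threshold
    high: 1000.0
    osc_fraction: 0.0
    osc_low: 10.0
    osc_high: 200.0
    saturation: 2000.0
    source: "ANSI/ASHRAE Standard 62.1"
  - name: HCHO
    unit: "mg/m3"
    mode: upper_threshold
    high: 0.04
    osc_fraction: 0.0
    osc_low: 0.001
    osc_high: 0.02
    saturation: 0.08
    source: "EPA Standard"
  - name: TVOC
    unit: "mg/m3"
    mode: upper_threshold
    high: 1.0
    osc_fraction: 0.0
    osc_low: 0.01
    osc_high: 0.3
    saturation: 2.0
    source: "World Health Organization"
  - name: PM2.5
    unit: "ug/m3"
    mode: upper_threshold
    high: 35.0
    osc_fraction: 0.0
    osc_low: 1.0
    osc_high: 10.0
    saturation: 70.0
    source: "EPA Standard"
  - name: PM10
    unit: "ug/m3"
    mode: upper_threshold
    high: 35.0
    osc_fraction: 0.0
    osc_low: 1.0
    osc_high: 15.0
    saturation: 70.0
    source: "EPA Standard"
  - name: I+
    unit: "ions/cm3"
    mode: upper_threshold
    high: 1000.0
    osc_fraction: 0.0
    osc_low: 50.0
    osc_high: 500.0
    saturation: 2000.0
    source: "Jayaratne et al.; Renye et al. (small-air-ion guidance)"
  - name: I-
    unit: "ions/cm3"
    mode: lower_threshold
    low: 1000.0
    osc_fraction: 0.0
    osc_low: 50.0
    osc_high: 500.0
    saturation: 0.0
    source: "Jayaratne et al.; Renye et al. (small-air-ion guidance)"
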