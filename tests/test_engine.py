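import numpy as np
import pytest
from hypothesis import given, strategies as st

from hmrisk import (
    Family,
    IndicatorSpec,
    Mode,
    RangeMode,
    ThresholdMode,
    classify,
    combine,
    hmr_env_range,
    hmr_env_threshold,
    hmr_osc_range,
    hmr_osc_threshold,
    overall_average,
    room_average,
    score_indicator,
    series_stats,
)
from hmrisk.engine import ComponentScore, EngineError, SeriesStats, round_display

from conftest import brute_force_osc, make_series


def stats_with(mean=0.0, exceed_high=0.0, exceed_low=0.0, osc_mean=0.0, osc_max=0.0):
    return SeriesStats(
        mean=mean, n=100, exceed_fraction_high=exceed_high, exceed_fraction_low=exceed_low,
        osc_sum=osc_mean * 10, osc_mean=osc_mean, osc_max=osc_max, n_pairs=10,
    )


RANGE_T = IndicatorSpec(name="T", mode=Mode.RANGE, low=16.0, high=24.0,
                        osc_low=0.5, osc_high=2.0)
UPPER = IndicatorSpec(name="HCHO", mode=Mode.UPPER_THRESHOLD, high=0.04,
                      saturation=0.08, osc_low=0.001, osc_high=0.02)
LOWER = IndicatorSpec(name="I-", mode=Mode.LOWER_THRESHOLD, low=1000.0,
                      saturation=0.0, osc_low=50.0, osc_high=500.0)


# ---------------------------------------------------------------------------
# Series statistics and the oscillation sum
# ---------------------------------------------------------------------------


def test_two_flat_days_give_24_unit_differences(specs):
    series = make_series([10.0] * 24 + [12.0] * 24)
    s = series_stats(series, specs["T"])
    assert s.osc_sum == 48.0
    assert s.osc_max == 2.0
    assert s.n_pairs == 24
    assert s.osc_mean == 2.0


def test_constant_series_has_zero_oscillation_and_exceedance(specs):
    s = series_stats(make_series([20.0] * 72), specs["T"])
    assert s.osc_sum == 0.0
    assert s.exceed_fraction_high == 0.0 and s.exceed_fraction_low == 0.0
    assert s.mean == 20.0 and s.n == 72


def test_oscillation_sum_matches_brute_force_oracle_with_gaps(specs):
    rng = np.random.default_rng(42)
    vals = rng.normal(20, 3, size=5 * 24)
    series = make_series(vals)
    # knock out some hours to exercise the pair-skipping rule
    keep = np.ones(len(vals), dtype=bool)
    keep[rng.choice(len(vals), size=15, replace=False)] = False
    gappy = type(series)(
        indicator="T", room="r", sensor_id="s", data=series.data[keep]
    )
    for s in (series, gappy):
        st_ = series_stats(s, specs["T"])
        total, n_pairs, biggest = brute_force_osc(s)
        assert st_.osc_sum == pytest.approx(total, abs=1e-9)
        assert st_.n_pairs == n_pairs
        assert st_.osc_max == pytest.approx(biggest, abs=1e-12)


def test_exceedance_fractions_respect_mode(specs):
    series = make_series([30.0] * 12 + [20.0] * 36, indicator="T")
    s = series_stats(series, specs["T"])
    assert s.exceed_fraction_high == pytest.approx(0.25)
    co2 = make_series([1500.0] * 24 + [500.0] * 24, indicator="CO2")
    s2 = series_stats(co2, specs["CO2"])
    assert s2.exceed_fraction_high == pytest.approx(0.5)
    assert s2.exceed_fraction_low == 0.0
    ion = make_series([800.0] * 36 + [1200.0] * 12, indicator="I-")
    s3 = series_stats(ion, specs["I-"])
    assert s3.exceed_fraction_low == pytest.approx(0.75)


def test_empty_series_rejected(specs):
    import pandas as pd
    from hmrisk import SensorSeries

    empty = SensorSeries(indicator="T", room="r", sensor_id="s",
                         data=pd.Series([], dtype=float, index=pd.DatetimeIndex([])))
    with pytest.raises(EngineError):
        series_stats(empty, specs["T"])


# ---------------------------------------------------------------------------
# Range-mode scores
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "mean, expected",
    [(20.0, 0.0), (24.0, 1.0), (16.0, -1.0), (19.9, -0.025), (30.0, 1.0), (5.0, -1.0)],
)
def test_range_env_is_affine_between_bounds_and_clamped(mean, expected):
    assert hmr_env_range(stats_with(mean=mean), RANGE_T) == pytest.approx(expected)


def test_range_env_exceedance_only_scores_zero_inside():
    for mean in (16.0, 19.0, 24.0):
        assert hmr_env_range(stats_with(mean=mean), RANGE_T, RangeMode.EXCEEDANCE_ONLY) == 0.0
    above = hmr_env_range(stats_with(mean=26.0), RANGE_T, RangeMode.EXCEEDANCE_ONLY)
    assert above == pytest.approx(0.5)  # 2 * 2 / 8
    below = hmr_env_range(stats_with(mean=14.0), RANGE_T, RangeMode.EXCEEDANCE_ONLY)
    assert below == pytest.approx(-0.5)


@pytest.mark.parametrize(
    "osc_mean, expected", [(1.25, 0.0), (2.0, 1.0), (0.5, -1.0), (5.0, 1.0)]
)
def test_range_osc_endpoints(osc_mean, expected):
    assert hmr_osc_range(stats_with(osc_mean=osc_mean), RANGE_T) == pytest.approx(expected)


def test_range_scores_reject_threshold_specs():
    with pytest.raises(EngineError):
        hmr_env_range(stats_with(), UPPER)
    with pytest.raises(EngineError):
        hmr_osc_range(stats_with(), UPPER)


# ---------------------------------------------------------------------------
# Threshold-mode scores
# ---------------------------------------------------------------------------


def test_threshold_env_zero_when_all_below():
    s = stats_with(mean=0.02, exceed_high=0.0)
    assert hmr_env_threshold(s, UPPER) == 0.0


def test_threshold_env_one_at_joint_saturation():
    s = stats_with(mean=0.08, exceed_high=1.0)
    assert hmr_env_threshold(s, UPPER) == 1.0


def test_threshold_env_blends_magnitude_and_frequency():
    # mean 0.07 over the 0.04 threshold with saturation 0.08: E_mag = 0.75
    s = stats_with(mean=0.07, exceed_high=0.717)
    assert hmr_env_threshold(s, UPPER) == pytest.approx(0.5 * 0.75 + 0.5 * 0.717)


def test_threshold_env_lower_mode_mirrors_deficit():
    assert hmr_env_threshold(stats_with(mean=1200.0, exceed_low=0.0), LOWER) == 0.0
    s = stats_with(mean=500.0, exceed_low=0.6)
    assert hmr_env_threshold(s, LOWER) == pytest.approx(0.5 * 0.5 + 0.5 * 0.6)
    assert hmr_env_threshold(stats_with(mean=0.0, exceed_low=1.0), LOWER) == 1.0


def test_threshold_env_verbatim_is_the_printed_normalisation():
    # printed map: 1 at the threshold, falling to -1 (clamped 0) at saturation
    assert hmr_env_threshold(stats_with(mean=0.04), UPPER, ThresholdMode.VERBATIM) == 1.0
    assert hmr_env_threshold(stats_with(mean=0.08), UPPER, ThresholdMode.VERBATIM) == 0.0
    assert hmr_env_threshold(stats_with(mean=0.06), UPPER, ThresholdMode.VERBATIM) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "osc_mean, osc_max, expected",
    [(0.0, 0.0, 0.0), (0.02, 0.02, 1.0), (0.0105, 0.02, 0.5)],
)
def test_threshold_osc_semantic_scale(osc_mean, osc_max, expected):
    s = stats_with(osc_mean=osc_mean, osc_max=osc_max)
    assert hmr_osc_threshold(s, UPPER) == pytest.approx(expected)


def test_threshold_osc_verbatim_saturates_with_semantic_at_max():
    s = stats_with(osc_mean=0.02, osc_max=0.02)
    assert hmr_osc_threshold(s, UPPER, ThresholdMode.VERBATIM) == 1.0
    # no variation beyond the safe floor: 0, not a division by zero
    s0 = stats_with(osc_mean=0.0005, osc_max=0.001)
    assert hmr_osc_threshold(s0, UPPER) == 0.0


@given(
    mag_a=st.floats(0, 1), mag_b=st.floats(0, 1),
    freq_a=st.floats(0, 1), freq_b=st.floats(0, 1),
)
def test_semantic_score_monotone_in_magnitude_and_frequency(mag_a, mag_b, freq_a, freq_b):
    lo_m, hi_m = sorted((mag_a, mag_b))
    lo_f, hi_f = sorted((freq_a, freq_b))
    span = UPPER.saturation - UPPER.high

    def score(m, f):
        return hmr_env_threshold(stats_with(mean=UPPER.high + m * span, exceed_high=f), UPPER)

    assert score(hi_m, lo_f) >= score(lo_m, lo_f)
    assert score(lo_m, hi_f) >= score(lo_m, lo_f)


# ---------------------------------------------------------------------------
# Aggregation (worked examples) and classification
# ---------------------------------------------------------------------------


def test_combine_is_the_exact_mean():
    assert combine(0.56, 0.88) == pytest.approx(0.72)
    assert combine(0.951, 0.167) == pytest.approx(0.559)
    assert round_display(combine(0.951, 0.167)) == 0.56
    assert combine(0.0, 0.0) == 0.0


def _scores(triples):
    return [ComponentScore(f"x{i}", *t, mode_used="m") for i, t in enumerate(triples)]


def test_room_average_reproduces_published_rows():
    env, osc, hmr = room_average(_scores([(0.14, 0.47, 0.3), (0.56, 0.88, 0.72), (-0.35, 0.66, 0.15)]))
    assert round_display(hmr) == 0.39
    assert round_display(env) == 0.12
    assert round_display(osc) == 0.67

    hmr_h_vals = [0.0009, 0.56, 0, 0, 0.0093, 0.29, 0.15]
    _, _, ra = room_average(_scores([(0, 0, v) for v in hmr_h_vals]))
    assert ra == pytest.approx(0.14431428571)
    assert round_display(ra, 3) == 0.144

    single = room_average(_scores([(0.1, 0.2, 0.15)]))
    assert single == pytest.approx((0.1, 0.2, 0.15))


def test_overall_average_reproduces_published_values():
    _, _, oa = overall_average([(0, 0, 0.39), (0, 0, 0.41)])
    assert round_display(oa, 1) == 0.4
    _, _, oa2 = overall_average([(0, 0, 0.144), (0, 0, 0.111)])
    assert oa2 == pytest.approx(0.1275)
    assert round_display(oa2, 3) == 0.128
    assert overall_average([(0.1, 0.2, 0.3)]) == pytest.approx((0.1, 0.2, 0.3))


def test_classification_bands_and_qualifiers():
    assert classify(0.4, Family.HMR_E).band == "moderate"
    assert classify(0.128, Family.HMR_H).band == "low"
    extreme = classify(-1.0, Family.HMR_E)
    assert (extreme.band, extreme.qualifier) == ("high", "deficit")
    assert str(extreme) == "high/deficit"
    assert classify(0.7, Family.HMR_E).qualifier == "excess"
    assert classify(0.5, Family.HMR_H).qualifier is None
    with pytest.raises(EngineError):
        classify(1.5, Family.HMR_E)
    with pytest.raises(EngineError):
        classify(-0.1, Family.HMR_H)


def test_score_indicator_stays_in_family_domain(specs):
    rng = np.random.default_rng(3)
    t = make_series(rng.normal(20, 5, size=96), indicator="T")
    s = score_indicator(t, specs["T"])
    assert all(-1 <= v <= 1 for v in s.triple)
    co2 = make_series(rng.normal(1000, 400, size=96).clip(0), indicator="CO2")
    s2 = score_indicator(co2, specs["CO2"])
    assert all(0 <= v <= 1 for v in s2.triple)
    assert s2.mode_used == "threshold_semantic"


def test_round_display_is_half_away_from_zero():
    assert round_display(0.125, 2) == 0.13
    assert round_display(-0.125, 2) == -0.13
    assert round_display(0.1443, 3) == 0.144
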