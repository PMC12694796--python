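"""Heritage Microclimate Risk (HMR) scoring engine.

Each indicator receives two components and their arithmetic mean:

* ``HMR_env`` — how the period-average of the indicator sits relative to its
  standard (acceptability range, or one-sided threshold);
* ``HMR_osc`` — how large the day-to-day same-hour oscillations are relative
  to the daily variation the standard allows;
* ``HMR = (HMR_env + HMR_osc) / 2``.

Range-mode indicators (exhibit-conservation index, HMR_E) score on
``[-1, +1]``: 0 at the middle of the acceptable range, +1 at/above the upper
bound (excess), -1 at/below the lower bound (deficit). Threshold-mode
indicators (human-health index, HMR_H) score on ``[0, 1]``: 0 when every
observation respects the threshold, rising with the magnitude and frequency
of exceedances.

Per-indicator scores aggregate by unweighted means: indicator -> room
average -> overall average, and the aggregate maps onto a three-band risk
scale (low / moderate / high).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .standards import (
    IndicatorSpec,
    Mode,
    effective_bounds,
    effective_osc_bounds,
)
from .timeseries import RoomDataset, SensorSeries


class EngineError(ValueError):
    """Raised on degenerate scoring configuration or out-of-domain input."""


class RangeMode(str, enum.Enum):
    """How range indicators are scored.

    ``range_verbatim`` is the published linear map (0 at the range midpoint,
    -1/+1 at the adjusted bounds). ``exceedance_only`` scores 0 anywhere
    inside the range and grows proportionally to the exceedance outside it.
    """

    VERBATIM = "range_verbatim"
    EXCEEDANCE_ONLY = "exceedance_only"


class ThresholdMode(str, enum.Enum):
    """How threshold indicators are scored.

    ``threshold_semantic`` (default) blends exceedance magnitude and
    exceedance frequency, 0 when all observations respect the threshold and
    1 at joint saturation. ``threshold_verbatim`` evaluates the printed
    linear normalisation directly (kept for auditability; note it scores
    *high* when the mean sits at the threshold and low near saturation, the
    opposite of the stated risk semantics).
    """

    SEMANTIC = "threshold_semantic"
    VERBATIM = "threshold_verbatim"


class Family(str, enum.Enum):
    HMR_E = "HMR_E"
    HMR_H = "HMR_H"


#: Default risk-band cut points on |score| (inferred from the published
#: anchors: 0.4 is "moderate", 0.128 is "low").
BAND_CUTS = (0.2, 0.6)

#: Indicators entering each index by default.
HMR_E_INDICATORS = ("T", "RH", "AL")
HMR_H_INDICATORS = ("CO2", "HCHO", "TVOC", "PM2.5", "PM10", "I+", "I-")


# ---------------------------------------------------------------------------
# Series statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeriesStats:
    """Summary statistics of one indicator series used by every score.

    ``osc_sum`` is the sum over consecutive-day pairs and hours of the
    absolute same-hour change |X(day k, hour j) - X(day k+1, hour j)|; pairs
    where either value is missing are skipped. ``osc_mean`` divides by the
    number of differences actually summed (``n_pairs``), ``osc_max`` is the
    largest single difference (0 when no pair exists).
    """

    mean: float
    n: int
    exceed_fraction_high: float
    exceed_fraction_low: float
    osc_sum: float
    osc_mean: float
    osc_max: float
    n_pairs: int


def series_stats(series: SensorSeries, spec: IndicatorSpec) -> SeriesStats:
    """Compute the per-series statistics feeding the HMR components."""
    if len(series) == 0:
        raise EngineError(f"{series.indicator}/{series.room}: empty series")
    vals = series.values
    n = len(vals)
    mean = float(vals.mean())

    if spec.mode is Mode.RANGE:
        lo, hi = effective_bounds(spec)
        exceed_high = float(np.mean(vals > hi))
        exceed_low = float(np.mean(vals < lo))
    elif spec.mode is Mode.UPPER_THRESHOLD:
        exceed_high = float(np.mean(vals > spec.threshold))
        exceed_low = 0.0
    else:  # lower threshold: risk is the deficit below the limit
        exceed_high = 0.0
        exceed_low = float(np.mean(vals < spec.threshold))

    # same-hour day-to-day differences: pivot to a (day x hour) matrix and
    # difference consecutive calendar days
    idx = series.timestamps
    frame = pd.DataFrame(
        {"day": idx.normalize(), "hour": idx.hour, "value": vals}
    )
    mat = frame.pivot_table(index="day", columns="hour", values="value", aggfunc="mean")
    mat = mat.reindex(pd.date_range(mat.index.min(), mat.index.max(), freq="D"))
    diffs = np.abs(np.diff(mat.to_numpy(), axis=0))
    diffs = diffs[np.isfinite(diffs)]
    # fsum: correctly rounded independent of summation order
    osc_sum = math.fsum(diffs)
    n_pairs = int(diffs.size)
    osc_mean = float(osc_sum / n_pairs) if n_pairs else 0.0
    osc_max = float(diffs.max()) if n_pairs else 0.0

    return SeriesStats(
        mean=mean,
        n=n,
        exceed_fraction_high=exceed_high,
        exceed_fraction_low=exceed_low,
        osc_sum=osc_sum,
        osc_mean=osc_mean,
        osc_max=osc_max,
        n_pairs=n_pairs,
    )


# ---------------------------------------------------------------------------
# Component scores
# ---------------------------------------------------------------------------


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def hmr_env_range(
    stats: SeriesStats, spec: IndicatorSpec, mode: RangeMode = RangeMode.VERBATIM
) -> float:
    """Mean-level score for a range indicator, on [-1, +1].

    Verbatim: ``1 - 2 * (hi - mean) / (hi - lo)`` with the osc-fraction
    adjusted bounds — an affine map putting the midpoint at 0 and the bounds
    at -1/+1, clamped. Exceedance-only: 0 inside the adjusted range,
    ``+-2 * overshoot / (hi - lo)`` outside, clamped.
    """
    if spec.mode is not Mode.RANGE:
        raise EngineError(f"{spec.name}: hmr_env_range requires a range-mode spec")
    lo, hi = effective_bounds(spec)
    if hi == lo:
        raise EngineError(f"{spec.name}: degenerate range (high == low after adjustment)")
    if mode is RangeMode.VERBATIM:
        raw = 1.0 - ((hi - stats.mean) / (hi - lo)) * 2.0
    else:
        if stats.mean > hi:
            raw = 2.0 * (stats.mean - hi) / (hi - lo)
        elif stats.mean < lo:
            raw = -2.0 * (lo - stats.mean) / (hi - lo)
        else:
            raw = 0.0
    return _clamp(raw, -1.0, 1.0)


def hmr_osc_range(stats: SeriesStats, spec: IndicatorSpec) -> float:
    """Oscillation score for a range indicator, on [-1, +1].

    ``1 - 2 * (osc_high - osc_mean) / (osc_high - osc_low)`` with the
    osc-fraction adjusted oscillation bounds: -1 when the mean daily
    oscillation sits at the allowed floor, +1 at (or beyond) the allowed
    ceiling.
    """
    if spec.mode is not Mode.RANGE:
        raise EngineError(f"{spec.name}: hmr_osc_range requires a range-mode spec")
    lo, hi = effective_osc_bounds(spec)
    if hi == lo:
        raise EngineError(f"{spec.name}: degenerate oscillation bounds")
    raw = 1.0 - ((hi - stats.osc_mean) / (hi - lo)) * 2.0
    return _clamp(raw, -1.0, 1.0)


def hmr_env_threshold(
    stats: SeriesStats,
    spec: IndicatorSpec,
    mode: ThresholdMode = ThresholdMode.SEMANTIC,
    alpha: float = 0.5,
) -> float:
    """Mean-level score for a threshold indicator, on [0, 1].

    Semantic (default): ``alpha * E_mag + (1 - alpha) * E_freq`` where
    ``E_mag`` is the mean's normalised exceedance of the threshold (0 at or
    below the threshold, 1 at the saturation value) and ``E_freq`` the
    fraction of observations exceeding it. For a lower threshold the axis is
    mirrored: risk is the deficit below the limit.

    Verbatim: ``1 - 2 * (P_mean - P_opt) / (P_max - P_opt)`` clamped to
    [0, 1] (the published normalisation, retained for audit).
    """
    if spec.mode not in (Mode.UPPER_THRESHOLD, Mode.LOWER_THRESHOLD):
        raise EngineError(f"{spec.name}: hmr_env_threshold requires a threshold-mode spec")
    p_opt = spec.threshold
    p_sat = spec.effective_saturation()
    if spec.mode is Mode.UPPER_THRESHOLD:
        span = p_sat - p_opt
        excess = stats.mean - p_opt
        freq = stats.exceed_fraction_high
    else:
        span = p_opt - p_sat
        excess = p_opt - stats.mean
        freq = stats.exceed_fraction_low
    if span <= 0:
        raise EngineError(f"{spec.name}: saturation must differ from the threshold in the risk direction")

    if mode is ThresholdMode.VERBATIM:
        raw = 1.0 - (excess / span) * 2.0
        return _clamp(raw, 0.0, 1.0)
    e_mag = _clamp(excess / span, 0.0, 1.0)
    return _clamp(alpha * e_mag + (1.0 - alpha) * freq, 0.0, 1.0)


def hmr_osc_threshold(
    stats: SeriesStats,
    spec: IndicatorSpec,
    mode: ThresholdMode = ThresholdMode.SEMANTIC,
) -> float:
    """Oscillation score for a threshold indicator, on [0, 1].

    Semantic (default): ``(dP_mean - dP_opt) / (dP_max - dP_opt)`` clamped —
    0 when the average day-to-day change sits at the safe floor
    (``spec.osc_low``), approaching 1 as it approaches the worst observed
    change. Verbatim evaluates ``1 - 2 * (dP_max - dP_mean) / (dP_max -
    dP_opt)`` clamped to [0, 1]. Both return 0 when the worst observed
    change does not exceed the safe floor.
    """
    if spec.mode not in (Mode.UPPER_THRESHOLD, Mode.LOWER_THRESHOLD):
        raise EngineError(f"{spec.name}: hmr_osc_threshold requires a threshold-mode spec")
    dp_opt = spec.osc_low
    dp_max = stats.osc_max
    dp_mean = stats.osc_mean
    if dp_max <= dp_opt:
        return 0.0
    if mode is ThresholdMode.VERBATIM:
        raw = 1.0 - ((dp_max - dp_mean) / (dp_max - dp_opt)) * 2.0
        return _clamp(raw, 0.0, 1.0)
    return _clamp((dp_mean - dp_opt) / (dp_max - dp_opt), 0.0, 1.0)


def combine(env: float, osc: float) -> float:
    """Combined index: the arithmetic mean of the two components."""
    if not (np.isfinite(env) and np.isfinite(osc)):
        raise EngineError("combine: components must be finite")
    return (env + osc) / 2.0


@dataclass(frozen=True)
class ComponentScore:
    """Per-indicator score triple (env, osc, combined) plus the mode used."""

    indicator: str
    hmr_env: float
    hmr_osc: float
    hmr: float
    mode_used: str

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.hmr_env, self.hmr_osc, self.hmr)


def score_indicator(
    series: SensorSeries,
    spec: IndicatorSpec,
    range_mode: RangeMode = RangeMode.VERBATIM,
    threshold_mode: ThresholdMode = ThresholdMode.SEMANTIC,
    alpha: float = 0.5,
) -> ComponentScore:
    """Score one indicator series against its standard."""
    stats = series_stats(series, spec)
    if spec.mode is Mode.RANGE:
        env = hmr_env_range(stats, spec, range_mode)
        osc = hmr_osc_range(stats, spec)
        mode_used = range_mode.value
    else:
        env = hmr_env_threshold(stats, spec, threshold_mode, alpha=alpha)
        osc = hmr_osc_threshold(stats, spec, threshold_mode)
        mode_used = threshold_mode.value
    return ComponentScore(
        indicator=spec.name,
        hmr_env=env,
        hmr_osc=osc,
        hmr=combine(env, osc),
        mode_used=mode_used,
    )


# ---------------------------------------------------------------------------
# Aggregation and classification
# ---------------------------------------------------------------------------


def room_average(scores: Sequence[ComponentScore]) -> tuple[float, float, float]:
    """Unweighted mean of (env, osc, combined) across a room's indicators."""
    if not scores:
        raise EngineError("room_average: no scores")
    env = float(np.mean([s.hmr_env for s in scores]))
    osc = float(np.mean([s.hmr_osc for s in scores]))
    hmr = float(np.mean([s.hmr for s in scores]))
    return (env, osc, hmr)


def overall_average(room_triples: Sequence[tuple[float, float, float]]) -> tuple[float, float, float]:
    """Unweighted mean of room-average triples across rooms."""
    if not room_triples:
        raise EngineError("overall_average: no rooms")
    arr = np.asarray(room_triples, dtype=float)
    return tuple(float(x) for x in arr.mean(axis=0))  # type: ignore[return-value]


@dataclass(frozen=True)
class RiskLabel:
    """Risk band with the deficit/excess qualifier for signed (HMR_E) scores."""

    band: str
    qualifier: Optional[str] = None

    def __str__(self) -> str:
        return f"{self.band}/{self.qualifier}" if self.qualifier else self.band


def classify(
    score: float,
    family: Family = Family.HMR_E,
    cuts: tuple[float, float] = BAND_CUTS,
) -> RiskLabel:
    """Map a score onto the three-band risk scale.

    |score| < cuts[0] is "low", below cuts[1] "moderate", otherwise "high".
    For the signed exhibit index a negative score carries the qualifier
    "deficit" (below-minimum conditions) and a positive score "excess".
    """
    family = Family(family)
    if family is Family.HMR_E:
        if not -1.0 <= score <= 1.0:
            raise EngineError(f"HMR_E score {score} outside [-1, 1]")
    else:
        if not 0.0 <= score <= 1.0:
            raise EngineError(f"HMR_H score {score} outside [0, 1]")
    mag = abs(score)
    if mag < cuts[0]:
        band = "low"
    elif mag < cuts[1]:
        band = "moderate"
    else:
        band = "high"
    qualifier = None
    if family is Family.HMR_E and score != 0.0:
        qualifier = "deficit" if score < 0 else "excess"
    return RiskLabel(band=band, qualifier=qualifier)


# ---------------------------------------------------------------------------
# Whole-assessment driver
# ---------------------------------------------------------------------------


@dataclass
class RoomResult:
    room: str
    scores: list[ComponentScore]
    average: tuple[float, float, float]
    label: RiskLabel


@dataclass
class RiskAssessment:
    """Per-room and overall aggregation of component scores for one index."""

    family: Family
    per_room: dict[str, RoomResult]
    overall: tuple[float, float, float]
    overall_label: RiskLabel
    missing: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self, decimals: Optional[int] = 2) -> pd.DataFrame:
        """Wide table: one row per component, one column per room x indicator
        plus room-average and overall-average columns."""
        cols: dict[tuple[str, str], list[float]] = {}
        for room, res in self.per_room.items():
            for s in res.scores:
                cols[(room, s.indicator)] = [s.hmr_env, s.hmr_osc, s.hmr]
            cols[(room, "Room average")] = list(res.average)
        cols[("", "Overall average")] = list(self.overall)
        frame = pd.DataFrame(cols, index=["HMR_env", "HMR_osc", self.family.value])
        frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["room", "indicator"])
        if decimals is not None:
            frame = frame.map(lambda v: round_display(v, decimals))
        return frame


def round_display(x: float, decimals: int = 2) -> float:
    """Round half away from zero, as the published tables do.

    Quantizes through eight guard digits first so that a decimal tie
    represented just below .5 in binary (e.g. mean(0.092, 0.075) = 0.0835)
    still rounds away from zero.
    """
    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal(1).scaleb(-(decimals + 8)), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def assess(
    datasets: Iterable[RoomDataset],
    specs: dict[str, IndicatorSpec],
    family: Family,
    indicators: Optional[Sequence[str]] = None,
    range_mode: RangeMode = RangeMode.VERBATIM,
    threshold_mode: ThresholdMode = ThresholdMode.SEMANTIC,
    alpha: float = 0.5,
    cuts: tuple[float, float] = BAND_CUTS,
) -> RiskAssessment:
    """Assess every room of a campaign for one index family.

    ``indicators`` defaults to the family's canonical set (T/RH/AL for the
    exhibit index; the seven pollutant indicators for the health index).
    Indicators missing from a room are recorded in ``missing`` and skipped,
    mirroring how each index is computed from whatever is available per room.
    """
    family = Family(family)
    if indicators is None:
        indicators = HMR_E_INDICATORS if family is Family.HMR_E else HMR_H_INDICATORS
    per_room: dict[str, RoomResult] = {}
    missing: dict[str, list[str]] = {}
    for ds in datasets:
        scores: list[ComponentScore] = []
        absent: list[str] = []
        for name in indicators:
            if name not in ds.series or name not in specs:
                absent.append(name)
                continue
            scores.append(
                score_indicator(
                    ds.series[name],
                    specs[name],
                    range_mode=range_mode,
                    threshold_mode=threshold_mode,
                    alpha=alpha,
                )
            )
        if absent:
            missing[ds.room] = absent
        if not scores:
            continue
        avg = room_average(scores)
        per_room[ds.room] = RoomResult(
            room=ds.room, scores=scores, average=avg, label=classify(avg[2], family, cuts)
        )
    if not per_room:
        raise EngineError(f"{family.value}: no room had any of the requested indicators")
    overall = overall_average([r.average for r in per_room.values()])
    return RiskAssessment(
        family=family,
        per_room=per_room,
        overall=overall,
        overall_label=classify(overall[2], family, cuts),
        missing=missing,
    )
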