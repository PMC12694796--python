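"""Hourly sensor time-series ingest, room aggregation and quality control.

The canonical container is :class:`SensorSeries`: the hourly observations of
one indicator from one sensor (or, after :func:`aggregate_room`, the
per-timestamp mean across all sensors of a room). Timestamps are treated as
local wall-clock hours; missing hours stay missing — they are excluded from
every count downstream, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .standards import IndicatorSpec, Mode

AGGREGATED = "<aggregated>"

CSV_COLUMNS = ["timestamp", "room", "sensor_id", "indicator", "value", "unit"]


class IngestError(ValueError):
    """Raised on malformed time-series input."""


@dataclass(frozen=True)
class SensorSeries:
    """Hourly observations of one indicator in one room.

    ``data`` is a float Series indexed by strictly increasing timestamps at
    (nominal) hourly cadence; gaps are simply absent index entries.
    """

    indicator: str
    room: str
    sensor_id: str
    data: pd.Series
    unit: str = ""
    aggregated: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise IngestError(f"{self.indicator}/{self.room}: index must be datetimes")
        if len(idx) and not idx.is_monotonic_increasing:
            raise IngestError(f"{self.indicator}/{self.room}: timestamps must be increasing")
        if idx.has_duplicates:
            raise IngestError(f"{self.indicator}/{self.room}: duplicate timestamps")
        if len(self.data) and not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise IngestError(f"{self.indicator}/{self.room}: non-finite values present")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index  # type: ignore[return-value]


@dataclass
class RoomDataset:
    """All aggregated series of one room plus its geometry metadata."""

    room: str
    series: dict[str, SensorSeries] = field(default_factory=dict)
    area_m2: Optional[float] = None
    volume_m3: Optional[float] = None

    def add(self, s: SensorSeries) -> None:
        if s.indicator in self.series:
            raise IngestError(f"room {self.room!r}: duplicate indicator {s.indicator!r}")
        self.series[s.indicator] = s


def read_timeseries(
    path: Union[str, Path],
    specs: Optional[dict[str, IndicatorSpec]] = None,
) -> list[SensorSeries]:
    """Read the standard long-format CSV into one series per (room, sensor, indicator).

    Expected header: ``timestamp,room,sensor_id,indicator,value,unit`` with
    ISO-8601 timestamps. Rows are sorted by time within each series. When a
    standards registry is supplied, units are checked against it; an unknown
    indicator produces a warning attribute, not an error.
    """
    df = pd.read_csv(
        path,
        dtype={"room": str, "sensor_id": str, "indicator": str, "unit": str},
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing columns {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise IngestError(f"{path}: unparseable timestamp at line {line}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna() & df["value"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise IngestError(f"{path}: non-numeric value at line {line}")
    df = df.assign(timestamp=ts, value=vals)

    dup = df.duplicated(subset=["timestamp", "room", "sensor_id", "indicator"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise IngestError(f"{path}: duplicate (timestamp, sensor, indicator) record at line {line}")

    out: list[SensorSeries] = []
    for (room, sensor_id, indicator), grp in df.groupby(
        ["room", "sensor_id", "indicator"], sort=True
    ):
        grp = grp.sort_values("timestamp")
        unit = str(grp["unit"].iloc[0]) if grp["unit"].notna().any() else ""
        if specs is not None and indicator in specs:
            expected = specs[indicator].unit
            if expected and unit and unit != expected:
                raise IngestError(
                    f"{path}: unit {unit!r} for {indicator} does not match standard {expected!r}"
                )
        data = pd.Series(
            grp["value"].to_numpy(dtype=float),
            index=pd.DatetimeIndex(grp["timestamp"]),
            name=indicator,
        ).dropna()
        out.append(
            SensorSeries(indicator=str(indicator), room=str(room), sensor_id=str(sensor_id), data=data, unit=unit)
        )
    return out


def write_timeseries(series: Iterable[SensorSeries], path: Union[str, Path]) -> None:
    """Write series to the standard long-format CSV (full float precision)."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": s.data.index.strftime("%Y-%m-%dT%H:%M:%S"),
                    "room": s.room,
                    "sensor_id": s.sensor_id,
                    "indicator": s.indicator,
                    "value": [repr(float(v)) for v in s.data.to_numpy()],
                    "unit": s.unit,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def aggregate_room(series: Sequence[SensorSeries]) -> SensorSeries:
    """Per-timestamp unweighted mean across all sensors of one room/indicator.

    At hours where only some sensors report, the mean is over the sensors
    that did report; hours with no sensor at all stay missing. A single
    already-aggregated series passes through unchanged (idempotent).
    """
    if not series:
        raise IngestError("aggregate_room: empty input")
    indicators = {s.indicator for s in series}
    rooms = {s.room for s in series}
    if len(indicators) > 1 or len(rooms) > 1:
        raise IngestError(f"aggregate_room: mixed inputs (indicators {indicators}, rooms {rooms})")
    if len(series) == 1:
        return replace(series[0], sensor_id=AGGREGATED, aggregated=True)
    wide = pd.concat({i: s.data for i, s in enumerate(series)}, axis=1).sort_index()
    mean = wide.mean(axis=1, skipna=True)
    return SensorSeries(
        indicator=series[0].indicator,
        room=series[0].room,
        sensor_id=AGGREGATED,
        data=mean,
        unit=series[0].unit,
        aggregated=True,
    )


def qc_report(series: SensorSeries, spec: Optional[IndicatorSpec] = None) -> dict:
    """Data-quality summary: gaps against the hourly cadence and implausible values.

    Physically implausible means a negative concentration for threshold-mode
    indicators or RH outside 0-100 %. Report-only; nothing is modified.
    """
    idx = series.timestamps
    n = len(idx)
    report: dict = {
        "indicator": series.indicator,
        "room": series.room,
        "n_observations": n,
    }
    if n == 0:
        report.update(n_expected=0, n_gaps=0, longest_gap_h=0, fraction_missing=0.0, n_implausible=0)
        return report
    expected = int((idx[-1] - idx[0]) / pd.Timedelta(hours=1)) + 1
    deltas = idx.to_series().diff().dropna() / pd.Timedelta(hours=1)
    gaps = deltas[deltas > 1.0]
    report["n_expected"] = expected
    report["n_gaps"] = int(len(gaps))
    report["longest_gap_h"] = int(gaps.max() - 1) if len(gaps) else 0
    report["fraction_missing"] = float((expected - n) / expected)

    vals = series.values
    implausible = np.zeros(len(vals), dtype=bool)
    if series.indicator.upper() == "RH":
        implausible |= (vals < 0) | (vals > 100)
    if spec is not None and spec.mode in (Mode.UPPER_THRESHOLD, Mode.LOWER_THRESHOLD):
        implausible |= vals < 0
    report["n_implausible"] = int(implausible.sum())
    return report
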