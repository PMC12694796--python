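"""Per-indicator standards registry.

Every HMR score is parameterised by an :class:`IndicatorSpec`: the acceptable
range or one-sided threshold an international standard prescribes for an
indoor-environment indicator, the daily oscillation band considered safe, and
(for threshold indicators) the saturation value at which the one-sided risk
score reaches 1.

Two scoring families exist:

* ``range`` indicators (temperature, relative humidity, artificial light)
  have a two-sided acceptability interval ``[low, high]``; risk is signed
  (negative = deficit below the range, positive = excess above it).
* ``upper_threshold`` / ``lower_threshold`` indicators (CO2, HCHO, TVOC,
  particulate matter, air ions) have a single bound; risk is one-sided on
  ``[0, 1]``.

A packaged default document (``data/table2_defaults.yaml``) carries the
standards used for museum exhibition spaces: T 16-24 degC, RH 45-60 %,
AL 50-200 lux, CO2 <= 1000 ppm, HCHO <= 0.04 mg/m3, TVOC <= 1 mg/m3,
PM2.5 and PM10 <= 35 ug/m3, positive ions <= 1000 ions/cm3 and negative
ions >= 1000 ions/cm3.
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class StandardsError(ValueError):
    """Raised when a standards document or spec is invalid."""


class Mode(str, enum.Enum):
    RANGE = "range"
    UPPER_THRESHOLD = "upper_threshold"
    LOWER_THRESHOLD = "lower_threshold"


class IndicatorSpec(BaseModel):
    """One monitored indicator's standard.

    Parameters
    ----------
    name:
        Indicator identifier (e.g. ``"T"``, ``"HCHO"``).
    unit:
        Measurement unit as free text.
    mode:
        ``range``, ``upper_threshold`` or ``lower_threshold``.
    low, high:
        The acceptability limits. A range needs both; an upper threshold
        needs ``high`` (the "must not exceed" value); a lower threshold
        needs ``low`` (the "must not fall below" value).
    osc_fraction:
        The oscillation fraction allowed by the standard, used to widen the
        range multiplicatively: the adjusted bounds are
        ``high * (1 + osc_fraction)`` and ``low * (1 - osc_fraction)``.
        Defaults to 0 so the published limits apply verbatim.
    osc_low, osc_high:
        Minimum and maximum allowed daily same-hour oscillation, the
        normalisation interval of the oscillation score.
    saturation:
        For threshold indicators, the value at which the one-sided risk
        score saturates at 1. Defaults to twice the threshold for upper
        thresholds and 0 for lower thresholds.
    source:
        Citation text for the issuing standard.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    unit: str = ""
    mode: Mode
    low: Optional[float] = None
    high: Optional[float] = None
    osc_fraction: float = 0.0
    osc_low: float = 0.0
    osc_high: float = 1.0
    saturation: Optional[float] = None
    source: str = ""

    @model_validator(mode="after")
    def _check(self) -> "IndicatorSpec":
        import math

        if self.mode is Mode.RANGE:
            if self.low is None or self.high is None:
                raise ValueError(f"{self.name}: range mode requires both low and high")
            if not self.low < self.high:
                raise ValueError(f"{self.name}: range requires low < high, got [{self.low}, {self.high}]")
        elif self.mode is Mode.UPPER_THRESHOLD:
            if self.high is None:
                raise ValueError(f"{self.name}: upper_threshold requires 'high'")
        elif self.mode is Mode.LOWER_THRESHOLD:
            if self.low is None:
                raise ValueError(f"{self.name}: lower_threshold requires 'low'")
        for field in ("osc_fraction", "osc_low", "osc_high"):
            v = getattr(self, field)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{self.name}: {field} must be finite and >= 0")
        if self.saturation is not None and not math.isfinite(self.saturation):
            raise ValueError(f"{self.name}: saturation must be finite")
        if self.saturation is not None and self.saturation < 0:
            raise ValueError(f"{self.name}: saturation must be >= 0")
        if not self.osc_high > self.osc_low:
            raise ValueError(f"{self.name}: osc_high must exceed osc_low")
        if self.mode is Mode.UPPER_THRESHOLD and self.saturation is not None:
            if self.saturation <= self.high:
                raise ValueError(f"{self.name}: saturation must exceed the upper threshold")
        if self.mode is Mode.LOWER_THRESHOLD and self.saturation is not None:
            if self.saturation >= self.low:
                raise ValueError(f"{self.name}: saturation must lie below the lower threshold")
        return self

    # -- derived quantities -------------------------------------------------

    @property
    def threshold(self) -> float:
        """The single limit of a threshold-mode spec (P_opt)."""
        if self.mode is Mode.UPPER_THRESHOLD:
            return self.high  # type: ignore[return-value]
        if self.mode is Mode.LOWER_THRESHOLD:
            return self.low  # type: ignore[return-value]
        raise StandardsError(f"{self.name}: range-mode spec has no single threshold")

    def effective_saturation(self) -> float:
        """Saturation value (P_max) with the documented defaults applied."""
        if self.saturation is not None:
            return self.saturation
        if self.mode is Mode.UPPER_THRESHOLD:
            return 2.0 * self.threshold
        if self.mode is Mode.LOWER_THRESHOLD:
            return 0.0
        raise StandardsError(f"{self.name}: saturation is undefined for range mode")


def effective_bounds(spec: IndicatorSpec) -> tuple[float, float]:
    """Adjusted range bounds: ``(low*(1-f), high*(1+f))`` with f = osc_fraction.

    The standard's limits are widened by the oscillation fraction it allows;
    with the default ``osc_fraction = 0`` the published limits are returned
    unchanged.
    """
    if spec.mode is not Mode.RANGE:
        raise StandardsError(f"{spec.name}: effective_bounds applies to range-mode specs only")
    return spec.low * (1.0 - spec.osc_fraction), spec.high * (1.0 + spec.osc_fraction)


def effective_osc_bounds(spec: IndicatorSpec) -> tuple[float, float]:
    """Adjusted daily-oscillation bounds, widened by osc_fraction like the range."""
    return spec.osc_low * (1.0 - spec.osc_fraction), spec.osc_high * (1.0 + spec.osc_fraction)


# -- document I/O ----------------------------------------------------------


def load_standards(source: Union[str, Path, dict]) -> list[IndicatorSpec]:
    """Load and validate a standards document (YAML/JSON path or parsed dict).

    The document is a mapping with an ``indicators`` list, one mapping per
    indicator, keys as in :class:`IndicatorSpec`. Duplicate indicator names
    are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    if not isinstance(doc, dict) or "indicators" not in doc:
        raise StandardsError("standards document must be a mapping with an 'indicators' list")
    specs: list[IndicatorSpec] = []
    seen: set[str] = set()
    for entry in doc["indicators"]:
        try:
            spec = IndicatorSpec(**entry)
        except ValueError as exc:
            raise StandardsError(str(exc)) from exc
        if spec.name in seen:
            raise StandardsError(f"duplicate indicator {spec.name!r} in standards document")
        seen.add(spec.name)
        specs.append(spec)
    return specs


def dump_standards(specs: Iterable[IndicatorSpec], path: Union[str, Path]) -> None:
    """Write specs back to a YAML document that :func:`load_standards` accepts."""
    entries = []
    for spec in specs:
        entry = spec.model_dump(mode="json", exclude_none=True)
        entries.append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"indicators": entries}, fh, sort_keys=False, allow_unicode=True)


def default_standards() -> list[IndicatorSpec]:
    """The packaged default standards document."""
    with resources.files("hmrisk").joinpath("data/table2_defaults.yaml").open("r") as fh:
        return load_standards(yaml.safe_load(fh))


def registry(specs: Iterable[IndicatorSpec]) -> dict[str, IndicatorSpec]:
    """Index specs by indicator name."""
    return {s.name: s for s in specs}
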