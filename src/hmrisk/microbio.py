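"""Colony-count quantitation and antimicrobial-persistence summaries.

Plate counts convert to colony-forming units per gram of sample as
``CFU/g = NCC * DF / VP`` (colony count x dilution factor / volume plated in
mL; the assay here uses a 1:50 dilution and 1 mL plated). Two censoring
states are carried through every comparison:

* ``below_detection`` — no countable colony at the plated dilution; reported
  as "< limit" (the conventional "< 10" report).
* ``uncountable`` — confluent growth above the countable ceiling (default
  300 colonies/plate, the standard plate-count convention); reported as
  "> ceiling * DF / VP".

The persistence summary compares a treated and an untreated arm of each
sample across two test dates, with every fold change and contrast aware of
censoring (comparisons against censored values are reported as bounds).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd


class MicrobioError(ValueError):
    """Raised on invalid colony records."""


class Arm(str, enum.Enum):
    UNTREATED = "untreated"
    TREATED = "treated"


class Test(str, enum.Enum):
    T1 = "t1"
    T2 = "t2"


class Censor(str, enum.Enum):
    BELOW_DETECTION = "below_detection"
    UNCOUNTABLE = "uncountable"


#: Countable ceiling per plate (colonies) above which a plate is "uncountable".
DEFAULT_COUNT_CEILING = 300

#: Reporting limit used for below-detection results, in CFU/g ("< 10").
DEFAULT_REPORTING_LIMIT = 10.0


@dataclass(frozen=True)
class ColonyRecord:
    """One plate: a colony count or censor mark with its dilution arithmetic."""

    sample_id: str
    arm: Arm
    test: Test
    ncc: Union[int, Censor]
    dilution_factor: float = 50.0
    volume_plated_ml: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.ncc, int):
            if self.ncc < 0:
                raise MicrobioError(f"{self.sample_id}: negative colony count")
        elif not isinstance(self.ncc, Censor):
            raise MicrobioError(f"{self.sample_id}: ncc must be an integer or a censor mark")
        if self.dilution_factor <= 0 or self.volume_plated_ml <= 0:
            raise MicrobioError(f"{self.sample_id}: DF and VP must be positive")


@dataclass(frozen=True)
class CfuResult:
    """CFU/g for one plate; ``censor`` marks bound-only results.

    ``cfu_per_g`` is the point value for numeric counts, the reporting limit
    for ``lt_limit`` results, and the ceiling-equivalent CFU/g for
    ``gt_limit`` results.
    """

    sample_id: str
    arm: Arm
    test: Test
    cfu_per_g: float
    censor: Optional[str]  # None | "lt_limit" | "gt_limit"
    detection_limit: float

    def display(self) -> str:
        if self.censor == "lt_limit":
            return f"< {self.cfu_per_g:g}"
        if self.censor == "gt_limit":
            return "Uncountable"
        return f"{self.cfu_per_g:g}"


def cfu_per_g(
    record: ColonyRecord,
    reporting_limit: float = DEFAULT_REPORTING_LIMIT,
    count_ceiling: int = DEFAULT_COUNT_CEILING,
) -> CfuResult:
    """Convert one plate record to CFU/g with censoring.

    Numeric counts use exact integer arithmetic scaled by DF/VP; a zero
    count is a below-detection report. The detection limit (one colony's
    CFU/g equivalent) is DF/VP.
    """
    df, vp = record.dilution_factor, record.volume_plated_ml
    det = df / vp
    if record.ncc == Censor.BELOW_DETECTION or record.ncc == 0:
        return CfuResult(record.sample_id, record.arm, record.test, reporting_limit, "lt_limit", det)
    if record.ncc == Censor.UNCOUNTABLE:
        return CfuResult(record.sample_id, record.arm, record.test, count_ceiling * det, "gt_limit", det)
    return CfuResult(record.sample_id, record.arm, record.test, record.ncc * df / vp, None, det)


def ncc_from_cfu(result: CfuResult, dilution_factor: float = 50.0, volume_plated_ml: float = 1.0) -> int:
    """Recover the colony count from a numeric CFU/g result (exact inverse)."""
    if result.censor is not None:
        raise MicrobioError("cannot recover a count from a censored result")
    ncc = result.cfu_per_g * volume_plated_ml / dilution_factor
    if abs(ncc - round(ncc)) > 1e-9:
        raise MicrobioError("CFU/g value is not a multiple of DF/VP")
    return int(round(ncc))


# ---------------------------------------------------------------------------
# Persistence summary (treated vs untreated across two test dates)
# ---------------------------------------------------------------------------


def _fold_change(t1: CfuResult, t2: CfuResult) -> tuple[Optional[float], str]:
    """Censoring-aware t1 -> t2 fold change: (value-or-bound, kind).

    kind is one of ``exact``, ``lower_bound`` (true fold is at least the
    value), ``upper_bound``, or ``indeterminate`` (both ends censored low —
    flagged stable-low).
    """
    c1, c2 = t1.censor, t2.censor
    if c1 is None and c2 is None:
        if t1.cfu_per_g == 0:
            return (math.inf, "exact") if t2.cfu_per_g > 0 else (None, "indeterminate")
        return (t2.cfu_per_g / t1.cfu_per_g, "exact")
    if c1 == "lt_limit" and c2 == "lt_limit":
        return (None, "indeterminate")
    if c1 == "lt_limit":  # t1 < limit: fold at least t2/limit
        return (t2.cfu_per_g / t1.cfu_per_g, "lower_bound")
    if c2 == "lt_limit":  # t2 < limit: fold at most limit/t1
        return (t2.cfu_per_g / t1.cfu_per_g, "upper_bound")
    if c2 == "gt_limit":  # t2 above ceiling: fold at least ceiling-equiv/t1
        return (t2.cfu_per_g / t1.cfu_per_g, "lower_bound")
    # c1 == "gt_limit"
    return (t2.cfu_per_g / t1.cfu_per_g, "upper_bound")


def _contrast(treated: CfuResult, untreated: CfuResult) -> str:
    """Order treated vs untreated at one test date, respecting censoring.

    Returns ``treated_lower`` / ``treated_higher`` / ``tie`` when the order
    is certain given the bounds, else ``indeterminate``.
    """
    tl = treated.censor == "lt_limit"
    ul = untreated.censor == "lt_limit"
    tg = treated.censor == "gt_limit"
    ug = untreated.censor == "gt_limit"
    t, u = treated.cfu_per_g, untreated.cfu_per_g
    if tl and ug:
        return "treated_lower"
    if tg and ul:
        return "treated_higher"
    if tl and not (ul or ug):
        return "treated_lower" if t <= u else "indeterminate"
    if ul and not (tl or tg):
        return "treated_higher" if u <= t else "indeterminate"
    if ug and not (tl or tg):
        return "treated_lower" if t <= u else "indeterminate"
    if tg and not (ul or ug):
        return "treated_higher" if u <= t else "indeterminate"
    if tl and ul or tg and ug:
        return "indeterminate"
    if t == u:
        return "tie"
    return "treated_lower" if t < u else "treated_higher"


def persistence_summary(
    records: Sequence[ColonyRecord],
    reporting_limit: float = DEFAULT_REPORTING_LIMIT,
    count_ceiling: int = DEFAULT_COUNT_CEILING,
) -> dict:
    """Summarise treated-vs-untreated persistence across the two test dates.

    Returns a dict with a per-sample DataFrame (CFU/g in all four cells,
    fold changes per arm, contrasts per test, a ``stable_low`` flag for
    treated arms censored low at both dates) and overall tallies, including
    the number of samples where the treated arm is below the untreated arm
    at the second test and a censoring-aware estimate of the log10 reduction.
    """
    key = {}
    for rec in records:
        k = (rec.sample_id, rec.arm, rec.test)
        if k in key and key[k].ncc != rec.ncc:
            raise MicrobioError(f"conflicting duplicate record for {k}")
        key[k] = rec
    results = {k: cfu_per_g(r, reporting_limit, count_ceiling) for k, r in key.items()}
    samples = sorted({k[0] for k in key})

    rows = []
    n_treated_lower_t2 = 0
    for sid in samples:
        cells = {
            (arm, test): results.get((sid, arm, test))
            for arm in (Arm.UNTREATED, Arm.TREATED)
            for test in (Test.T1, Test.T2)
        }
        row: dict = {"sample_id": sid}
        for (arm, test), res in cells.items():
            row[f"{arm.value}_{test.value}"] = res.display() if res else ""
        for arm in (Arm.UNTREATED, Arm.TREATED):
            a, b = cells[(arm, Test.T1)], cells[(arm, Test.T2)]
            if a and b:
                fold, kind = _fold_change(a, b)
                row[f"{arm.value}_fold_change"] = fold
                row[f"{arm.value}_fold_kind"] = kind
            else:
                row[f"{arm.value}_fold_change"] = None
                row[f"{arm.value}_fold_kind"] = "missing"
        for test in (Test.T1, Test.T2):
            tr, un = cells[(Arm.TREATED, test)], cells[(Arm.UNTREATED, test)]
            row[f"contrast_{test.value}"] = _contrast(tr, un) if tr and un else "missing"
        t1, t2 = cells[(Arm.TREATED, Test.T1)], cells[(Arm.TREATED, Test.T2)]
        row["stable_low"] = bool(
            t1 and t2 and t1.censor == "lt_limit" and t2.censor == "lt_limit"
        )
        if row["contrast_t2"] == "treated_lower":
            n_treated_lower_t2 += 1
        rows.append(row)

    table = pd.DataFrame(rows)
    return {
        "table": table,
        "n_samples": len(samples),
        "n_treated_lower_t2": n_treated_lower_t2,
        "estimated_log10_reduction": estimate_log10_reduction(records, count_ceiling),
    }


def estimate_log10_reduction(
    records: Sequence[ColonyRecord], count_ceiling: int = DEFAULT_COUNT_CEILING
) -> Optional[float]:
    """log10(mean untreated count / mean treated count) across all plates.

    Below-detection plates contribute a count of 0 and uncountable plates
    the ceiling, so the estimate is a lower bound when uncountable plates
    are present. Returns None when either arm is absent or its mean is 0.
    """
    def counts(arm: Arm) -> list[float]:
        out = []
        for r in records:
            if r.arm is not arm:
                continue
            if r.ncc == Censor.BELOW_DETECTION:
                out.append(0.0)
            elif r.ncc == Censor.UNCOUNTABLE:
                out.append(float(count_ceiling))
            else:
                out.append(float(r.ncc))
        return out

    u, t = counts(Arm.UNTREATED), counts(Arm.TREATED)
    if not u or not t:
        return None
    mu, mt = float(np.mean(u)), float(np.mean(t))
    if mu <= 0 or mt <= 0:
        return None
    return math.log10(mu / mt)


# ---------------------------------------------------------------------------
# Simulation and I/O
# ---------------------------------------------------------------------------


def simulate_assay(
    mean_colonies: float,
    log10_reduction: float,
    n_samples: int,
    seed: int,
    dilution_factor: float = 50.0,
    volume_plated_ml: float = 1.0,
    count_ceiling: int = DEFAULT_COUNT_CEILING,
    tests: Sequence[Test] = (Test.T1,),
) -> list[ColonyRecord]:
    """Simulate a paired plate-count assay.

    Untreated plate counts are Poisson(mean_colonies); treated counts are
    Poisson(mean_colonies * 10**(-log10_reduction)). Counts above the
    countable ceiling become ``uncountable`` marks and zeros become
    ``below_detection``, as a real plate reader would report them.
    """
    if mean_colonies <= 0:
        raise MicrobioError("mean_colonies must be positive")
    if log10_reduction < 0:
        raise MicrobioError("log10_reduction must be >= 0")
    if n_samples <= 0:
        raise MicrobioError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    records: list[ColonyRecord] = []
    means = {Arm.UNTREATED: mean_colonies, Arm.TREATED: mean_colonies * 10.0 ** (-log10_reduction)}
    for i in range(n_samples):
        sid = f"S{i + 1:03d}"
        for test in tests:
            for arm in (Arm.UNTREATED, Arm.TREATED):
                count = int(rng.poisson(means[arm]))
                ncc: Union[int, Censor]
                if count == 0:
                    ncc = Censor.BELOW_DETECTION
                elif count > count_ceiling:
                    ncc = Censor.UNCOUNTABLE
                else:
                    ncc = count
                records.append(
                    ColonyRecord(sid, arm, test, ncc, dilution_factor, volume_plated_ml)
                )
    return records


def read_colony_csv(path: Union[str, Path]) -> list[ColonyRecord]:
    """Read colony records from CSV:
    ``sample_id,arm,test,ncc_or_mark,dilution_factor,volume_plated_ml``."""
    df = pd.read_csv(path, dtype={"sample_id": str, "arm": str, "test": str, "ncc_or_mark": str})
    required = ["sample_id", "arm", "test", "ncc_or_mark"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MicrobioError(f"{path}: missing columns {missing}")
    if df.empty:
        raise MicrobioError(f"{path}: no records")
    records = []
    for i, row in df.iterrows():
        raw = str(row["ncc_or_mark"]).strip()
        ncc: Union[int, Censor]
        if raw in (Censor.BELOW_DETECTION.value, Censor.UNCOUNTABLE.value):
            ncc = Censor(raw)
        else:
            try:
                ncc = int(raw)
            except ValueError as exc:
                raise MicrobioError(f"{path} line {int(i) + 2}: bad count {raw!r}") from exc
        try:
            records.append(
                ColonyRecord(
                    sample_id=str(row["sample_id"]),
                    arm=Arm(str(row["arm"])),
                    test=Test(str(row["test"])),
                    ncc=ncc,
                    dilution_factor=float(row.get("dilution_factor", 50.0) or 50.0),
                    volume_plated_ml=float(row.get("volume_plated_ml", 1.0) or 1.0),
                )
            )
        except ValueError as exc:
            raise MicrobioError(f"{path} line {int(i) + 2}: {exc}") from exc
    return records


def write_colony_csv(records: Iterable[ColonyRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "arm": r.arm.value,
            "test": r.test.value,
            "ncc_or_mark": r.ncc.value if isinstance(r.ncc, Censor) else r.ncc,
            "dilution_factor": r.dilution_factor,
            "volume_plated_ml": r.volume_plated_ml,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
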