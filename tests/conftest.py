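import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hmrisk import SensorSeries, default_standards, registry

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specs():
    """Packaged default standards, keyed by indicator name."""
    return registry(default_standards())


def make_series(values, indicator="T", room="EH 1-2", sensor_id="s1",
                start="2024-01-01", freq="h", unit=""):
    """Build a SensorSeries from a plain value list."""
    vals = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(vals), freq=freq)
    return SensorSeries(
        indicator=indicator, room=room, sensor_id=sensor_id,
        data=pd.Series(vals, index=idx, name=indicator), unit=unit,
    )


def brute_force_osc(series):
    """Independent oracle for the day-to-day same-hour oscillation sum.

    Walks every (calendar day, hour) cell with an explicit double loop and
    accumulates |X(day k, hour j) - X(day k+1, hour j)| over consecutive-day
    pairs where both values exist.
    """
    lookup = {}
    for ts, v in series.data.items():
        lookup[(ts.normalize(), ts.hour)] = float(v)
    days = sorted({d for d, _ in lookup})
    if not days:
        return 0.0, 0, 0.0
    import math

    collected = []
    day = days[0]
    while day < days[-1]:
        nxt = day + pd.Timedelta(days=1)
        for hour in range(24):
            a, b = lookup.get((day, hour)), lookup.get((nxt, hour))
            if a is not None and b is not None:
                collected.append(abs(a - b))
        day = nxt
    total = math.fsum(collected)
    return total, len(collected), max(collected, default=0.0)
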