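"""Per-dive shape metrics.

Eight variables describe a dive's shape: maximum depth, duration, bottom
time (time at >= 85 % of maximum depth), the two skew ratios
(ascent/descent rate and its reciprocal), and three derived ratios — bottom
time / duration (BTD), bottom time / max depth (BTM) and max depth /
duration (MDD).  Wiggles (vertical reversals within the bottom phase) are
counted separately and collapsed to a wiggle-dive indicator for
classification.  Dive shapes divide broadly into *square* dives (a high
fraction of the dive spent at depth, the classical foraging signature) and
*V-shaped* dives (brief bottom phase, associated with travel/exploration).

Conventions, fixed here once for reproducibility:

* a dive window covers consecutive submerged samples with inclusive 0-based
  indices; duration = (number of samples) * dt;
* the bottom phase is every sample with depth >= bottom_fraction * max depth;
* a wiggle is a local depth minimum within the bottom span whose adjacent
  fall and rise each exceed ``wiggle_min_excursion`` (default 1 m, twice
  the 0.5 m transducer resolution), counted on the plateau-collapsed series
  with the span endpoints acting as boundary extrema;
* descent rate = depth of the first bottom-phase sample divided by the
  elapsed time from the window start to that sample (one dt if it is the
  first sample); ascent rate is the mirror image at the window end.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .solar import DEFAULT_LAT, DEFAULT_LON, DEFAULT_UTC_OFFSET, monthly_sun_table
from .trace import DepthTrace, DiveWindow

__all__ = [
    "DiveRecord",
    "compute_metrics",
    "count_wiggles",
    "label_shape",
    "assign_context",
    "dive_table",
    "BREEDING_MONTHS",
    "DEEP_THRESHOLD",
]

#: July-October: pupping plus breeding phenology in the Salish Sea.
BREEDING_MONTHS = frozenset({7, 8, 9, 10})

#: Depth (m) separating "deep" from "shallow" dives and bouts.
DEEP_THRESHOLD = 20.0


@dataclass
class DiveRecord:
    """One detected dive with its shape metrics."""

    animal_id: str
    start_s: float
    end_s: float
    max_depth: float
    duration: float
    bottom_time: float
    wiggles: int
    skew1: float  # ascent rate / descent rate
    skew2: float  # descent rate / ascent rate
    btd: float  # bottom time / duration
    btm: float  # bottom time / max depth (s/m)
    mdd: float  # max depth / duration (m/s)
    descent_rate: float
    ascent_rate: float
    is_wiggle_dive: bool
    shape_class: str = ""  # square | V
    depth_class: str = ""  # deep | shallow
    assigned_type: int | None = None


def count_wiggles(depths: np.ndarray, excursion: float = 1.0) -> int:
    """Count qualifying local depth minima in a bottom-phase segment.

    Consecutive equal samples are collapsed first, so segments alternate
    strictly; a minimum qualifies when the fall from the preceding turning
    point (or segment start) and the rise to the following turning point
    (or segment end) both exceed ``excursion``.
    """
    d = np.asarray(depths, dtype=float)
    if d.size < 3:
        return 0
    keep = np.concatenate([[True], np.diff(d) != 0])
    v = d[keep]
    if v.size < 3:
        return 0
    interior = np.arange(1, v.size - 1)
    is_turn = (v[interior] - v[interior - 1]) * (v[interior + 1] - v[interior]) < 0
    turns = np.concatenate([[0], interior[is_turn], [v.size - 1]])
    count = 0
    for j in range(1, turns.size - 1):
        t = turns[j]
        if v[t] < v[turns[j - 1]] and v[t] < v[turns[j + 1]]:
            if (v[turns[j - 1]] - v[t]) > excursion and (
                v[turns[j + 1]] - v[t]
            ) > excursion:
                count += 1
    return count


def compute_metrics(
    trace: DepthTrace,
    window: DiveWindow,
    bottom_fraction: float = 0.85,
    wiggle_min_excursion: float = 1.0,
) -> DiveRecord:
    """Compute the shape metrics of one dive window (conventions above)."""
    d = trace.depth[window.start : window.end + 1]
    dt = trace.dt
    max_depth = float(d.max())
    duration = d.size * dt
    bottom = d >= bottom_fraction * max_depth
    bottom_idx = np.flatnonzero(bottom)
    bottom_time = bottom_idx.size * dt
    first_b, last_b = int(bottom_idx[0]), int(bottom_idx[-1])
    wiggles = count_wiggles(d[first_b : last_b + 1], wiggle_min_excursion)
    descent_rate = float(d[first_b]) / max(first_b * dt, dt)
    ascent_rate = float(d[last_b]) / max((d.size - 1 - last_b) * dt, dt)
    skew1 = ascent_rate / descent_rate
    return DiveRecord(
        animal_id=trace.animal_id,
        start_s=float(trace.time[window.start]),
        end_s=float(trace.time[window.end]) + dt,
        max_depth=max_depth,
        duration=duration,
        bottom_time=bottom_time,
        wiggles=wiggles,
        skew1=skew1,
        skew2=1.0 / skew1,
        btd=bottom_time / duration,
        btm=bottom_time / max_depth,
        mdd=max_depth / duration,
        descent_rate=descent_rate,
        ascent_rate=ascent_rate,
        is_wiggle_dive=wiggles > 0,
        depth_class="deep" if max_depth >= DEEP_THRESHOLD else "shallow",
    )


def label_shape(record_or_btd, square_btd_threshold: float = 0.5) -> str:
    """Square vs V dive shape from the bottom-time/duration ratio.

    Square dives spend at least half the dive at depth (boundary
    inclusive); everything below the threshold is V-shaped.
    """
    btd = getattr(record_or_btd, "btd", record_or_btd)
    return "square" if btd >= square_btd_threshold else "V"


def dive_table(
    trace: DepthTrace,
    windows: list[DiveWindow],
    bottom_fraction: float = 0.85,
    wiggle_min_excursion: float = 1.0,
) -> pd.DataFrame:
    """Metrics for every window as a tidy DataFrame (one row per dive)."""
    records = [
        compute_metrics(trace, w, bottom_fraction, wiggle_min_excursion)
        for w in windows
    ]
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        return df
    df["shape_class"] = [label_shape(r) for r in records]
    if trace.start is not None:
        df["start"] = [trace.start + timedelta(seconds=s) for s in df["start_s"]]
    return df


def assign_context(
    dives: pd.DataFrame,
    sun_table: pd.DataFrame | None = None,
    breeding_months: frozenset[int] = BREEDING_MONTHS,
    lat: float = DEFAULT_LAT,
    lon: float = DEFAULT_LON,
    utc_offset: float = DEFAULT_UTC_OFFSET,
) -> pd.DataFrame:
    """Attach season (breeding/non-breeding) and light (day/night) labels.

    ``sun_table`` holds mean sunrise/sunset clock hours per month (index
    month 1-12, columns ``sunrise``/``sunset``).  Months absent from the
    table fall back to the built-in solar approximation at (lat, lon).  A
    dive is a day dive when its start lies in [mean sunrise, mean sunset)
    for the month — the half-open convention puts a dive starting exactly
    at sunset in the night class.
    """
    if "start" not in dives.columns:
        raise ValueError("dive table needs a 'start' datetime column")
    out = dives.copy()
    months = pd.DatetimeIndex(out["start"]).month
    out["season"] = np.where(
        np.isin(months, list(breeding_months)), "breeding", "non-breeding"
    )
    fallback: pd.DataFrame | None = None
    light = []
    for ts, month in zip(out["start"], months):
        ts = pd.Timestamp(ts)
        if sun_table is not None and month in sun_table.index:
            rise = float(sun_table.loc[month, "sunrise"])
            sett = float(sun_table.loc[month, "sunset"])
        else:
            if fallback is None:
                fallback = monthly_sun_table(ts.year, lat, lon, utc_offset)
            rise = float(fallback.loc[month, "sunrise"])
            sett = float(fallback.loc[month, "sunset"])
        hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
        light.append("day" if rise <= hour < sett else "night")
    out["light"] = light
    return out
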