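"""Sequential bout detection and bout summary variables.

Diving predators rarely forage with single dives; dives cluster into
*bouts*.  Bouts are found with an iterative sequential criterion in the
Boyd tradition: a bout opens at a run of at least four consecutive dives
to at least 6 m, and each following dive joins unless its preceding
surface interval is *significantly greater* than the surface intervals
already inside the bout, judged by a one-sided single-new-observation
t-test at alpha = 0.05.  With k previous intervals of mean m and sample
standard deviation s, the statistic for the next interval x is

    t = (x - m) / (s * sqrt(1 + 1/k)),   df = k - 1,

the prediction-interval form for one new observation.  A non-positive
statistic can never be significant, so an interval equal to (or below)
the running mean always joins.  When the history has zero variance the
statistic degenerates to +/- infinity and the sign of x - m decides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BoutConfig",
    "Bout",
    "detect_bouts",
    "summarize_bout",
    "bout_table",
    "fraction_outside_bouts",
]


@dataclass(frozen=True)
class BoutConfig:
    """Bout start rule and extension-test settings."""

    start_min_dives: int = 4
    start_min_depth: float = 6.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.start_min_dives < 2:
            raise ValueError("start_min_dives must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class Bout:
    """A maximal run of dives passing the sequential-interval test."""

    animal_id: str
    dive_indices: list  # positional indices into the (sorted) dive table
    n_dives: int
    mean_depth: float
    mean_duration: float
    mean_surface_interval: float
    bout_duration: float
    pct_time_at_depth: float
    pct_square: float
    pct_v: float
    assigned_type: str | None = None
    covariates: dict = field(default_factory=dict)


def _next_interval_significant(
    intervals: list[float], x: float, alpha: float
) -> bool:
    """One-sided test: is the next surface interval significantly greater?"""
    k = len(intervals)
    m = float(np.mean(intervals))
    s = float(np.std(intervals, ddof=1))
    if s == 0.0:
        return x > m
    t = (x - m) / (s * np.sqrt(1.0 + 1.0 / k))
    return t > stats.t.ppf(1.0 - alpha, k - 1)


def detect_bouts(
    dives: pd.DataFrame,
    config: BoutConfig = BoutConfig(),
) -> tuple[list[Bout], list[int]]:
    """Partition time-ordered dives into bouts (per animal).

    ``dives`` needs columns ``animal_id``, ``start_s``, ``end_s`` and
    ``max_depth``.  The surface interval preceding dive j is
    ``start_s[j] - end_s[j-1]`` within the same animal.  Scanning left to
    right, a bout opens at the first run of ``start_min_dives`` consecutive
    dives with ``max_depth >= start_min_depth``; the extension test then
    grows it dive by dive, and when an interval is significantly long the
    bout closes before it and scanning resumes at the dive that failed.
    Returns the bouts plus the positional indices of unassigned dives.
    """
    bouts: list[Bout] = []
    assigned: set[int] = set()
    n_total = len(dives)
    positions = np.arange(n_total)
    for animal, sub in dives.groupby("animal_id", sort=False):
        pos = positions[dives["animal_id"].to_numpy() == animal]
        starts = sub["start_s"].to_numpy(dtype=float)
        ends = sub["end_s"].to_numpy(dtype=float)
        depths = sub["max_depth"].to_numpy(dtype=float)
        gaps = starts[1:] - ends[:-1]  # gap[i] precedes dive i+1
        n = len(sub)
        m0 = config.start_min_dives
        i = 0
        while i + m0 <= n:
            if not np.all(depths[i : i + m0] >= config.start_min_depth):
                i += 1
                continue
            members = list(range(i, i + m0))
            intervals = [float(g) for g in gaps[i : i + m0 - 1]]
            j = i + m0 - 1
            while j + 1 < n:
                x = float(gaps[j])
                if _next_interval_significant(intervals, x, config.alpha):
                    break
                members.append(j + 1)
                intervals.append(x)
                j += 1
            member_pos = [int(pos[k]) for k in members]
            assigned.update(member_pos)
            bouts.append(
                summarize_bout(dives.iloc[member_pos], intervals, member_pos)
            )
            i = j + 1
    unassigned = [int(p) for p in positions if p not in assigned]
    return bouts, unassigned


def summarize_bout(
    member_dives: pd.DataFrame,
    intervals: list[float] | None = None,
    member_positions: list[int] | None = None,
) -> Bout:
    """The eight bout variables from a bout's member dives.

    ``intervals`` are the within-bout surface intervals; when omitted they
    are recomputed from the member dives' start/end times.  Covariates
    (site, season, sex, light) are carried by majority vote over member
    dives, ties resolved by the first dive.
    """
    if len(member_dives) < 2:
        raise ValueError("a bout needs at least 2 member dives")
    starts = member_dives["start_s"].to_numpy(dtype=float)
    ends = member_dives["end_s"].to_numpy(dtype=float)
    if intervals is None:
        intervals = list(starts[1:] - ends[:-1])
    bout_duration = float(ends[-1] - starts[0])
    covariates = {}
    for cov in ("site", "season", "sex", "light"):
        if cov in member_dives.columns:
            vals = member_dives[cov]
            counts = vals.value_counts()
            top = counts[counts == counts.max()].index
            covariates[cov] = (
                vals.iloc[0] if len(top) > 1 else top[0]
            )
    shapes = member_dives["shape_class"].to_numpy()
    pct_square = float(np.mean(shapes == "square"))
    return Bout(
        animal_id=str(member_dives["animal_id"].iloc[0]),
        dive_indices=(
            member_positions
            if member_positions is not None
            else list(range(len(member_dives)))
        ),
        n_dives=len(member_dives),
        mean_depth=float(member_dives["max_depth"].mean()),
        mean_duration=float(member_dives["duration"].mean()),
        mean_surface_interval=float(np.mean(intervals)),
        bout_duration=bout_duration,
        pct_time_at_depth=float(member_dives["bottom_time"].sum() / bout_duration),
        pct_square=pct_square,
        pct_v=1.0 - pct_square,
        covariates=covariates,
    )


def bout_table(bouts: list[Bout]) -> pd.DataFrame:
    """Bouts as a tidy DataFrame, one row per bout."""
    rows = []
    for b in bouts:
        row = {
            "animal_id": b.animal_id,
            "n_dives": b.n_dives,
            "mean_depth": b.mean_depth,
            "mean_duration": b.mean_duration,
            "mean_surface_interval": b.mean_surface_interval,
            "bout_duration": b.bout_duration,
            "pct_time_at_depth": b.pct_time_at_depth,
            "pct_square": b.pct_square,
            "pct_v": b.pct_v,
            "assigned_type": b.assigned_type,
        }
        row.update(b.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def fraction_outside_bouts(
    dives: pd.DataFrame, bouts: list[Bout]
) -> float:
    """Proportion of dives not belonging to any bout."""
    if len(dives) == 0:
        raise ValueError("fraction undefined: no dives")
    in_bouts = sum(b.n_dives for b in bouts)
    return 1.0 - in_bouts / len(dives)
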