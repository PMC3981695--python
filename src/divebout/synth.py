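"""Synthetic TDR traces, dive/bout metric tables, and bout-type outcomes.

The generators emulate the statistical structure the analysis assumes, so
the whole pipeline can be exercised and validated without field data:

* six parametric dive-shape templates (four square, two V-shaped)
  parameterized by published means and SDs of harbor-seal dive types:
  trapezoidal profiles for square dives, triangles for V dives, and
  sinusoidal bottom oscillations for wiggles;
* bouts of dives with lognormal within-bout surface intervals, a clearly
  separated between-bout gap distribution, and an optional fraction of
  isolated (non-bout) dives;
* a factorial covariate/outcome table drawn from the hierarchical
  logistic bout-type model itself, with known coefficients and per-seal
  random effects, for parameter-recovery experiments.

Positive quantities (depths, durations, intervals, skews) are drawn from
moment-matched lognormals: they are strictly positive and right-skewed in
real dive records, and the lognormal reproduces a published mean +/- SD
exactly.  Ground truth (shape ids, bout membership, boundaries, true
coefficients) is always returned alongside, never embedded in the trace
format, so synthetic data flow through the same I/O paths as real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd

from . import bayes
from .trace import DepthTrace

__all__ = [
    "DiveShapeParams",
    "BoutTypeGenParams",
    "BoutGenParams",
    "BoutSummaryParams",
    "OutcomeGenParams",
    "DEFAULT_DIVE_SHAPES",
    "DEFAULT_BOUT_TYPES",
    "DEFAULT_BOUT_SUMMARIES",
    "TABLE5_BETA",
    "sample_dive_metrics",
    "sample_bout_metrics",
    "generate_trace",
    "generate_outcomes",
    "add_drift",
]


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws matching the requested mean and SD exactly."""
    if sd <= 0:
        return np.full(size, float(mean)) if size else float(mean)
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size)


def _trunc_lognormal(rng, mean, sd, lower, size=None):
    """Lognormal draws resampled until strictly above ``lower``."""
    x = np.atleast_1d(np.asarray(_lognormal(rng, mean, sd, size), dtype=float))
    bad = x <= lower
    guard = 0
    while bad.any():
        x[bad] = np.atleast_1d(_lognormal(rng, mean, sd, int(bad.sum())))
        bad = x <= lower
        guard += 1
        if guard > 1000:
            raise RuntimeError("truncated sampling failed; check parameters")
    return x if size is not None else float(x[0])


@dataclass(frozen=True)
class DiveShapeParams:
    """Mean/SD parameterization of one dive type's shape variables."""

    shape_id: int
    max_depth: tuple[float, float]  # m
    duration: tuple[float, float]  # s
    bottom_time: tuple[float, float]  # s
    wiggles: tuple[float, float]  # count
    skew1: tuple[float, float]  # ascent/descent rate ratio
    skew2: tuple[float, float] = (0.0, 0.0)  # reference only (= 1/skew1)
    descent_rate: tuple[float, float] = (0.0, 0.0)  # reference only
    ascent_rate: tuple[float, float] = (0.0, 0.0)  # reference only

    def __post_init__(self) -> None:
        for name in ("max_depth", "duration", "bottom_time", "skew1"):
            mean, sd = getattr(self, name)
            if mean <= 0 and name != "bottom_time":
                raise ValueError(f"{name} mean must be positive")
            if sd < 0:
                raise ValueError(f"{name} SD must be nonnegative")
        if self.wiggles[0] < 0 or self.wiggles[1] < 0:
            raise ValueError("wiggle parameters must be nonnegative")
        if self.bottom_time[0] >= self.duration[0]:
            raise ValueError("bottom_time mean must be below duration mean")

    @property
    def is_square(self) -> bool:
        return self.bottom_time[0] / self.duration[0] >= 0.5


#: Published mean +/- SD of the six harbor-seal dive types (types 1-3 and 6
#: square, 4-5 V-shaped; 1, 2 and partially 4, 5 carry wiggles).
DEFAULT_DIVE_SHAPES = [
    DiveShapeParams(1, (62.0, 30.65), (310.14, 107.69), (181.62, 96.69),
                    (1.05, 0.38), (0.94, 0.26), (1.14, 0.36), (1.11, 0.33),
                    (1.0, 0.3)),
    DiveShapeParams(2, (13.36, 7.19), (219.27, 99.57), (152.81, 89.11),
                    (1.04, 0.29), (1.01, 0.48), (1.18, 0.51), (0.54, 0.26),
                    (0.5, 0.25)),
    DiveShapeParams(3, (56.23, 23.51), (304.58, 78.48), (192.14, 76.16),
                    (0.0, 0.0), (0.95, 0.23), (1.11, 0.26), (1.1, 0.33),
                    (1.02, 0.33)),
    DiveShapeParams(4, (17.55, 12.8), (148.73, 73.77), (39.51, 29.53),
                    (0.46, 0.51), (1.8, 1.17), (0.71, 0.29), (0.42, 0.27),
                    (0.61, 0.37)),
    DiveShapeParams(5, (16.13, 12.68), (166.45, 73.92), (60.03, 46.45),
                    (0.35, 0.48), (0.47, 0.17), (2.64, 2.54), (0.65, 0.67),
                    (0.29, 0.18)),
    DiveShapeParams(6, (13.57, 7.71), (241.79, 106.89), (179.79, 100.31),
                    (0.0, 0.0), (1.04, 0.48), (1.12, 0.43), (0.52, 0.26),
                    (0.5, 0.25)),
]


@dataclass(frozen=True)
class BoutTypeGenParams:
    """Per-bout-type generation parameters for trace synthesis."""

    name: str
    weight: float
    n_dives: tuple[float, float]
    dive_depth: tuple[float, float]  # m, per-dive max depth within the bout
    surface_interval: tuple[float, float]  # s, within-bout
    square_frac: float  # dive-shape mixture: P(square)

    def __post_init__(self) -> None:
        if not 0.0 <= self.square_frac <= 1.0:
            raise ValueError("square_frac must lie in [0, 1]")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


#: Bout-level generation defaults from the published bout-type summaries:
#: deep foraging (I), shallow foraging/traveling (II) and rare resting
#: bouts with very long surface intervals (III).
DEFAULT_BOUT_TYPES = [
    BoutTypeGenParams("I", 0.60, (5.82, 2.71), (44.73, 27.45),
                      (45.46, 28.25), 0.95),
    BoutTypeGenParams("II", 0.39, (5.63, 2.35), (18.97, 11.47),
                      (39.22, 61.37), 0.44),
    BoutTypeGenParams("III", 0.01, (5.47, 3.11), (18.86, 12.84),
                      (3139.46, 2254.39), 0.53),
]


@dataclass(frozen=True)
class BoutGenParams:
    """Bout mixture plus between-bout structure for trace synthesis.

    The gap following a bout is lognormal with mean
    ``max(between_bout_gap mean, 10 x that bout type's surface-interval
    mean)`` — a separated distribution, so the sequential bout test has
    signal to work with, and resting bouts (internal intervals near an
    hour) end at haul-out-scale gaps.  ``isolated_fraction`` inserts lone
    dives amounting to that fraction of all dives; they emulate the
    single shallow dives tied to haul-out/resting behavior seen outside
    bouts, with depths drawn between the 5 m analysis threshold and the
    6 m bout-start depth (``isolated_depth_range``).  A *deep* lone dive
    is not representable as outside-bout structure: under the sequential
    rule it would simply seed a bout with whatever dives follow.
    """

    bout_types: tuple[BoutTypeGenParams, ...] = tuple(DEFAULT_BOUT_TYPES)
    between_bout_gap: tuple[float, float] = (600.0, 300.0)
    isolated_fraction: float = 0.0
    isolated_depth_range: tuple[float, float] = (5.3, 5.95)

    def __post_init__(self) -> None:
        w = sum(t.weight for t in self.bout_types)
        if not np.isclose(w, 1.0):
            raise ValueError("bout-type weights must sum to 1")
        if not 0.0 <= self.isolated_fraction < 1.0:
            raise ValueError("isolated_fraction must lie in [0, 1)")


# ---------------------------------------------------------------------------
# dive metric sampling (no trace construction)
# ---------------------------------------------------------------------------


def _draw_shape(
    rng: np.random.Generator,
    p: DiveShapeParams,
    sd_scale: float,
    dt: float,
    depth: float | None = None,
) -> dict:
    """Draw one dive's core quantities and derive the dependent metrics.

    The derivation mirrors the profile geometry: a plateau of length
    bt = (B - 0.15 D) / 0.85 at full depth reproduces a measured bottom
    time of exactly B (samples within 15 % of the maximum depth on the
    descent/ascent ramps contribute the rest), and splitting the transit
    time in the ratio skew1 = t_descent / t_ascent reproduces the drawn
    skew when rates are measured to the bottom-phase boundary.
    """
    M = depth if depth is not None else _trunc_lognormal(
        rng, p.max_depth[0], p.max_depth[1] * sd_scale, 5.0
    )
    D = _trunc_lognormal(rng, p.duration[0], p.duration[1] * sd_scale, 5 * dt)
    B = (
        0.0
        if p.bottom_time[0] <= 0
        else min(
            _lognormal(rng, p.bottom_time[0], p.bottom_time[1] * sd_scale),
            0.9 * D,
        )
    )
    if p.wiggles[1] <= 0:
        w = int(round(p.wiggles[0]))
    else:
        w = max(0, int(round(rng.normal(p.wiggles[0], p.wiggles[1] * sd_scale))))
    s1 = _trunc_lognormal(rng, p.skew1[0], p.skew1[1] * sd_scale, 0.05)
    plateau = max((B - 0.15 * D) / 0.85, 0.0)
    transit = D - plateau
    t_d = transit * s1 / (1.0 + s1)
    t_a = transit - t_d
    bottom = plateau + 0.15 * transit
    return dict(
        shape_id=p.shape_id,
        max_depth=M,
        duration=D,
        bottom_time=bottom,
        wiggles=w,
        skew1=s1,
        skew2=1.0 / s1,
        btd=bottom / D,
        btm=bottom / M,
        mdd=M / D,
        descent_rate=M / t_d,
        ascent_rate=M / t_a,
        is_wiggle_dive=w > 0,
        _plateau=plateau,
        _t_d=t_d,
        _t_a=t_a,
    )


def sample_dive_metrics(
    shape_params: list[DiveShapeParams] | None = None,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    sd_scale: float = 1.0,
    weights: list[float] | None = None,
    dt: float = 10.0,
) -> pd.DataFrame:
    """Draw dive metric vectors directly from the shape templates.

    Returns one row per dive with the eight classification variables, the
    wiggle indicator, and the generating ``shape_id`` as ground truth.
    ``sd_scale`` shrinks every SD (0.5 gives the well-separated regime
    used for recovery experiments).
    """
    params = shape_params or DEFAULT_DIVE_SHAPES
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w = np.asarray(weights if weights is not None else [1.0] * len(params))
    w = w / w.sum()
    picks = rng.choice(len(params), size=n, p=w)
    rows = [_draw_shape(rng, params[i], sd_scale, dt) for i in picks]
    df = pd.DataFrame(rows).drop(columns=["_plateau", "_t_d", "_t_a"])
    return df


@dataclass(frozen=True)
class BoutSummaryParams:
    """Mean/SD parameterization of one bout type's eight summary variables."""

    name: str
    n_dives: tuple[float, float]
    mean_depth: tuple[float, float]
    mean_duration: tuple[float, float]
    mean_surface_interval: tuple[float, float]
    bout_duration: tuple[float, float]
    pct_time_at_depth: tuple[float, float]
    pct_square: tuple[float, float]


#: Published bout-type summaries (deep foraging, shallow foraging/travel,
#: long-surface-interval resting).
DEFAULT_BOUT_SUMMARIES = [
    BoutSummaryParams("I", (5.82, 2.71), (44.73, 27.45), (288.93, 84.88),
                      (45.46, 28.25), (2267.70, 1071.29), (0.55, 0.13),
                      (0.95, 0.09)),
    BoutSummaryParams("II", (5.63, 2.35), (18.97, 11.47), (165.59, 57.57),
                      (39.22, 61.37), (1355.34, 739.92), (0.33, 0.13),
                      (0.44, 0.24)),
    BoutSummaryParams("III", (5.47, 3.11), (18.86, 12.84), (193.34, 81.54),
                      (3139.46, 2254.39), (20214.87, 12765.20), (0.04, 0.03),
                      (0.53, 0.28)),
]


def sample_bout_metrics(
    summary_params: list[BoutSummaryParams] | None = None,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    sd_scale: float = 1.0,
    weights: list[float] | None = None,
) -> pd.DataFrame:
    """Draw bout summary vectors directly from the bout-type summaries."""
    params = summary_params or DEFAULT_BOUT_SUMMARIES
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w = np.asarray(
        weights if weights is not None else [0.60, 0.39, 0.01][: len(params)]
    )
    w = w / w.sum()
    picks = rng.choice(len(params), size=n, p=w)
    rows = []
    for i in picks:
        p = params[i]
        nd = max(4, int(round(rng.normal(p.n_dives[0], p.n_dives[1] * sd_scale))))
        tad = float(
            np.clip(
                _lognormal(rng, p.pct_time_at_depth[0],
                           p.pct_time_at_depth[1] * sd_scale),
                0.003, 1.0,
            )
        )
        psq = float(
            np.clip(rng.normal(p.pct_square[0], p.pct_square[1] * sd_scale),
                    0.0, 1.0)
        )
        rows.append(
            dict(
                bout_type=p.name,
                n_dives=nd,
                mean_depth=_trunc_lognormal(
                    rng, p.mean_depth[0], p.mean_depth[1] * sd_scale, 1.0
                ),
                mean_duration=_trunc_lognormal(
                    rng, p.mean_duration[0], p.mean_duration[1] * sd_scale, 10.0
                ),
                mean_surface_interval=_trunc_lognormal(
                    rng,
                    p.mean_surface_interval[0],
                    p.mean_surface_interval[1] * sd_scale,
                    1.0,
                ),
                bout_duration=_trunc_lognormal(
                    rng, p.bout_duration[0], p.bout_duration[1] * sd_scale, 60.0
                ),
                pct_time_at_depth=tad,
                pct_square=psq,
                pct_v=1.0 - psq,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trace construction
# ---------------------------------------------------------------------------


def _dive_profile(draw: dict, dt: float) -> np.ndarray:
    """Sample a dive template at the recorder grid (midpoint sampling).

    Square dives are trapezoids (linear descent, plateau, linear ascent);
    V dives degenerate to triangles; wiggles are sinusoidal oscillations
    on the plateau with amplitude capped at 15 % of the maximum depth so
    every wiggle stays inside the bottom phase.
    """
    M, w = draw["max_depth"], draw["wiggles"]
    n = max(5, int(round(draw["duration"] / dt)))
    total = n * dt
    scale = total / draw["duration"]
    t_d = draw["_t_d"] * scale
    plateau = draw["_plateau"] * scale
    t_a = draw["_t_a"] * scale
    t = (np.arange(n) + 0.5) * dt
    depth = np.empty(n)
    descend = t < t_d
    ascend = t >= t_d + plateau
    mid = ~descend & ~ascend
    depth[descend] = M * t[descend] / t_d
    depth[ascend] = M * (total - t[ascend]) / t_a
    if plateau > 0:
        u = t[mid] - t_d
        if w > 0:
            amp = min(0.15 * M, max(1.6, 0.1 * M))
            depth[mid] = M - amp * (0.5 - 0.5 * np.cos(2 * np.pi * w * u / plateau))
        else:
            depth[mid] = M
    return depth


def generate_trace(
    shape_params: list[DiveShapeParams] | None = None,
    bout_params: BoutGenParams | None = None,
    n_bouts: int = 10,
    dt: float = 10.0,
    seed: int | np.random.Generator = 0,
    sd_scale: float = 1.0,
    surface_threshold: float = 2.0,
    lead: int = 30,
    animal_id: str = "sim",
    start: datetime | None = None,
) -> tuple[DepthTrace, pd.DataFrame]:
    """Generate a depth trace organized into bouts, with ground truth.

    Returns the trace plus a sidecar table with one row per generated
    dive: realized sample boundaries (first/last submerged sample), the
    generating shape id, bout membership (-1 for isolated dives), bout
    type, and whether the dive is detectable under the standard filters
    (run length >= 5 samples, max depth > 5 m).  Identical seeds give
    bitwise-identical output.
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    shapes = shape_params or DEFAULT_DIVE_SHAPES
    bp = bout_params or BoutGenParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    squares = [p for p in shapes if p.is_square]
    vees = [p for p in shapes if not p.is_square]
    weights = np.array([t.weight for t in bp.bout_types])
    weights = weights / weights.sum()

    segments: list[np.ndarray] = [np.zeros(lead)]
    pos = lead
    truth_rows = []

    def emit_dive(template: DiveShapeParams, depth: float | None,
                  bout_id: int, bout_type: str) -> None:
        nonlocal pos
        draw = _draw_shape(rng, template, sd_scale, dt, depth=depth)
        profile = _dive_profile(draw, dt)
        segments.append(profile)
        truth_rows.append(
            dict(
                span_start=pos,
                span_end=pos + profile.size - 1,
                shape_id=template.shape_id,
                bout_id=bout_id,
                bout_type=bout_type,
                planned_max_depth=draw["max_depth"],
                planned_duration=draw["duration"],
                planned_bottom_time=draw["bottom_time"],
                planned_wiggles=draw["wiggles"],
                planned_skew1=draw["skew1"],
            )
        )
        pos += profile.size

    def emit_surface(seconds: float) -> None:
        nonlocal pos
        ns = max(1, int(round(seconds / dt)))
        segments.append(np.zeros(ns))
        pos += ns

    total_bout_dives = 0
    for b in range(n_bouts):
        btype = bp.bout_types[rng.choice(len(bp.bout_types), p=weights)]
        nd = max(4, int(round(rng.normal(btype.n_dives[0], btype.n_dives[1]))))
        total_bout_dives += nd
        for j in range(nd):
            is_square = rng.random() < btype.square_frac
            pool = squares if is_square else vees
            template = pool[rng.integers(len(pool))]
            depth = _trunc_lognormal(
                rng, btype.dive_depth[0], btype.dive_depth[1] * sd_scale, 6.0
            )
            emit_dive(template, depth, b, btype.name)
            if j < nd - 1:
                emit_surface(
                    _trunc_lognormal(
                        rng,
                        btype.surface_interval[0],
                        btype.surface_interval[1] * sd_scale,
                        dt / 2,
                    )
                )
        gap_mean = max(bp.between_bout_gap[0], 10.0 * btype.surface_interval[0])
        gap_sd = max(bp.between_bout_gap[1], gap_mean / 2.0)
        emit_surface(_trunc_lognormal(rng, gap_mean, gap_sd, 2 * dt))
        # sprinkle isolated (shallow resting) dives between bouts
        if bp.isolated_fraction > 0:
            want = bp.isolated_fraction / (1 - bp.isolated_fraction)
            n_iso_so_far = sum(1 for r in truth_rows if r["bout_id"] < 0)
            if n_iso_so_far < want * total_bout_dives:
                template = squares[rng.integers(len(squares))]
                iso_depth = rng.uniform(*bp.isolated_depth_range)
                emit_dive(template, iso_depth, -1, "isolated")
                emit_surface(
                    _trunc_lognormal(rng, *bp.between_bout_gap, 2 * dt)
                )
    segments.append(np.zeros(lead))
    depth_series = np.concatenate(segments)
    trace = DepthTrace(
        depth=depth_series, dt=dt, animal_id=animal_id, start=start
    )
    truth = pd.DataFrame(truth_rows)
    # realized submerged run inside each dive's sample span
    starts, ends, maxes, detectable = [], [], [], []
    for r in truth.itertuples():
        seg = depth_series[r.span_start : r.span_end + 1]
        sub = np.flatnonzero(seg > surface_threshold)
        if sub.size == 0:
            starts.append(-1); ends.append(-1)
            maxes.append(float(seg.max())); detectable.append(False)
            continue
        s, e = int(sub[0]), int(sub[-1])
        peak = float(seg[s : e + 1].max())
        starts.append(r.span_start + s)
        ends.append(r.span_start + e)
        maxes.append(peak)
        detectable.append((e - s + 1) >= 5 and peak > 5.0)
    truth["start_idx"] = starts
    truth["end_idx"] = ends
    truth["realized_max_depth"] = maxes
    truth["detectable"] = detectable
    return trace, truth


def add_drift(trace: DepthTrace, offset: float = 0.0, slope: float = 0.0):
    """Add a constant + linear transducer drift (slope in m per second)."""
    drift = offset + slope * trace.time
    return replace(trace, depth=trace.depth + drift)


# ---------------------------------------------------------------------------
# covariate / outcome generation for the Bayesian model
# ---------------------------------------------------------------------------

#: Published posterior means of the fixed effects (logit scale).  The
#: published model omitted the season x light two-way and the four-way
#: interaction, so those coefficients default to zero in the 16-term
#: full-factorial parameterization.
TABLE5_BETA = {
    "Intercept": 0.811,
    "Site1": 1.188,
    "Season1": -1.118,
    "Light1": -0.810,
    "Sex1": -3.309,
    "Site1:Season1": 1.03,
    "Site1:Light1": -0.143,
    "Site1:Sex1": 2.15,
    "Season1:Light1": 0.0,
    "Season1:Sex1": 0.98,
    "Light1:Sex1": 1.272,
    "Site1:Season1:Light1": 0.911,
    "Site1:Season1:Sex1": -1.906,
    "Site1:Light1:Sex1": -1.557,
    "Season1:Light1:Sex1": -0.039,
    "Site1:Season1:Light1:Sex1": 0.0,
}

_LEVELS = {
    "site": ("Bird Rocks", "Padilla Bay"),
    "season": ("breeding", "non-breeding"),
    "light": ("day", "night"),
    "sex": ("female", "male"),
}


@dataclass(frozen=True)
class OutcomeGenParams:
    """True coefficients and design settings for outcome generation.

    Site and sex are seal-level covariates (a seal has one haul-out site
    and one sex) assigned in balanced alternation; season and light vary
    per bout with the given non-reference-level frequencies.
    """

    beta: dict = field(default_factory=lambda: dict(TABLE5_BETA))
    sigma_alpha: float = 0.9
    n_seals: int = 21
    bouts_per_seal: int = 100
    level_freq: dict = field(
        default_factory=lambda: {"season": 0.5, "light": 0.5}
    )

    def __post_init__(self) -> None:
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be >= 0")
        if self.n_seals < 2:
            raise ValueError("need at least 2 seals")


def generate_outcomes(
    params: OutcomeGenParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Simulate covariates and bout-type labels from the logistic model.

    Returns ``(bouts, alpha_true, beta_true)``: a bout table with columns
    animal_id, site, season, sex, light and bout_type ("I"/"II"), the
    per-seal random effects actually drawn, and the coefficient vector in
    design order.  Labels follow Bernoulli(logit^-1(x' beta + alpha_i)).
    """
    p = params or OutcomeGenParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    seal_ids = [f"S{i:02d}" for i in range(p.n_seals)]
    site = [_LEVELS["site"][i % 2] for i in range(p.n_seals)]
    sex = [_LEVELS["sex"][(i // 2) % 2] for i in range(p.n_seals)]
    rows = []
    for i, sid in enumerate(seal_ids):
        for _ in range(p.bouts_per_seal):
            rows.append(
                dict(
                    animal_id=sid,
                    site=site[i],
                    season=_LEVELS["season"][
                        int(rng.random() < p.level_freq.get("season", 0.5))
                    ],
                    sex=sex[i],
                    light=_LEVELS["light"][
                        int(rng.random() < p.level_freq.get("light", 0.5))
                    ],
                )
            )
    bouts = pd.DataFrame(rows)
    bouts["bout_type"] = "I"  # placeholder so build_design has a response
    design = bayes.build_design(bouts, order=4)
    beta_true = pd.Series(
        [float(p.beta.get(name, 0.0)) for name in design.xnames],
        index=design.xnames,
    )
    alpha_true = (
        rng.normal(0.0, p.sigma_alpha, p.n_seals)
        if p.sigma_alpha > 0
        else np.zeros(p.n_seals)
    )
    eta = design.X @ beta_true.to_numpy() + alpha_true[design.seal_index]
    y = rng.random(len(bouts)) < bayes.logit_inv(eta)
    bouts["bout_type"] = np.where(y, "II", "I")
    return bouts, alpha_true, beta_true
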