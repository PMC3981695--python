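"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written as plain per-sample loops, separate
from the package's vectorized code paths, so agreement is a genuine
two-route check and not a tautology.
"""

from __future__ import annotations

import statistics

import numpy as np
from scipy import integrate, optimize, stats


def dive_metrics_oracle(depths, dt, bottom_fraction=0.85, excursion=1.0):
    """Per-sample recomputation of the dive shape metrics.

    Returns a dict with max_depth, duration, bottom_time, wiggles, rates
    and the derived ratios, following the stated conventions: bottom phase
    = samples at >= bottom_fraction * max depth; wiggles = local minima of
    the plateau-collapsed bottom span whose adjacent fall and rise both
    exceed the excursion; rates measured to the bottom-phase boundaries.
    """
    d = [float(x) for x in depths]
    n = len(d)
    max_depth = max(d)
    duration = n * dt
    cutoff = bottom_fraction * max_depth
    bottom = [i for i in range(n) if d[i] >= cutoff]
    bottom_time = len(bottom) * dt
    fb, lb = bottom[0], bottom[-1]

    seg = d[fb : lb + 1]
    collapsed = []
    for x in seg:
        if not collapsed or collapsed[-1] != x:
            collapsed.append(x)
    turns = [0]
    for i in range(1, len(collapsed) - 1):
        if (collapsed[i] - collapsed[i - 1]) * (
            collapsed[i + 1] - collapsed[i]
        ) < 0:
            turns.append(i)
    turns.append(len(collapsed) - 1)
    wiggles = 0
    for j in range(1, len(turns) - 1):
        t = turns[j]
        prev_v = collapsed[turns[j - 1]]
        next_v = collapsed[turns[j + 1]]
        v = collapsed[t]
        if v < prev_v and v < next_v:
            if (prev_v - v) > excursion and (next_v - v) > excursion:
                wiggles += 1

    descent_rate = d[fb] / max(fb * dt, dt)
    ascent_rate = d[lb] / max((n - 1 - lb) * dt, dt)
    skew1 = ascent_rate / descent_rate
    return dict(
        max_depth=max_depth,
        duration=duration,
        bottom_time=bottom_time,
        wiggles=wiggles,
        descent_rate=descent_rate,
        ascent_rate=ascent_rate,
        skew1=skew1,
        skew2=1.0 / skew1,
        btd=bottom_time / duration,
        btm=bottom_time / max_depth,
        mdd=max_depth / duration,
    )


def detect_dives_oracle(depths, surface_threshold, min_depth, min_samples):
    """Quadratic-ish plain scan for maximal submerged runs."""
    n = len(depths)
    out = []
    i = 0
    while i < n:
        if depths[i] > surface_threshold:
            j = i
            while j + 1 < n and depths[j + 1] > surface_threshold:
                j += 1
            run = [depths[k] for k in range(i, j + 1)]
            if len(run) >= min_samples and max(run) > min_depth:
                out.append((i, j, max(run)))
            i = j + 1
        else:
            i += 1
    return out


def detect_bouts_oracle(starts, ends, depths, min_dives=4, min_depth=6.0,
                        alpha=0.05):
    """From-scratch sequential bout partition for one animal.

    Recomputes the interval mean and SD from scratch at every step with
    the ``statistics`` module and judges significance through the t
    survival function (p < alpha) rather than a critical value, so the
    route differs from the implementation.  Returns (list of member index
    lists, unassigned indices).
    """
    n = len(starts)
    gaps = [starts[i + 1] - ends[i] for i in range(n - 1)]
    bouts = []
    used = set()
    i = 0
    while i + min_dives <= n:
        if not all(depths[i + k] >= min_depth for k in range(min_dives)):
            i += 1
            continue
        members = list(range(i, i + min_dives))
        intervals = [gaps[i + k] for k in range(min_dives - 1)]
        j = i + min_dives - 1
        while j + 1 < n:
            x = gaps[j]
            m = statistics.fmean(intervals)
            s = statistics.stdev(intervals)
            if s == 0:
                significant = x > m
            else:
                t = (x - m) / (s * (1 + 1 / len(intervals)) ** 0.5)
                significant = stats.t.sf(t, len(intervals) - 1) < alpha
            if significant:
                break
            members.append(j + 1)
            intervals.append(x)
            j += 1
        bouts.append(members)
        used.update(members)
        i = j + 1
    unassigned = [k for k in range(n) if k not in used]
    return bouts, unassigned


def intercept_posterior_oracle(successes=7, trials=10, prior_sd=10.0):
    """Adaptive-quadrature posterior mean and 2.5/97.5 % quantiles for the
    intercept-only binomial-logit model."""

    def unnorm(b):
        return np.exp(
            successes * b
            - trials * np.logaddexp(0.0, b)
            - 0.5 * (b / prior_sd) ** 2
        )

    z, _ = integrate.quad(unnorm, -30, 30)
    mean, _ = integrate.quad(lambda b: b * unnorm(b), -30, 30)
    mean /= z

    def cdf(x):
        v, _ = integrate.quad(unnorm, -30, x)
        return v / z

    q025 = optimize.brentq(lambda x: cdf(x) - 0.025, -30, 30)
    q975 = optimize.brentq(lambda x: cdf(x) - 0.975, -30, 30)
    return mean, q025, q975


def random_dive_sequence(rng, n, haulout_prob=0.15):
    """A randomized per-animal dive sequence exercising boundary cases.

    Mixes tight within-run intervals, occasional huge gaps, stretches of
    exactly constant intervals (zero-variance history) and intervals
    exactly equal to the running mean (t = 0), plus shallow dives that
    cannot seed a bout.
    """
    starts, ends, depths = [], [], []
    t = 0.0
    const_interval = float(rng.integers(30, 90))
    for i in range(n):
        dur = float(rng.integers(5, 40)) * 10.0
        starts.append(t)
        ends.append(t + dur)
        mode = rng.random()
        if mode < haulout_prob:
            gap = float(rng.integers(100, 5000))
        elif mode < 0.45:
            gap = const_interval  # exact repeats -> zero-variance history
        else:
            gap = float(rng.integers(20, 140))
        depths.append(float(rng.choice([4.0, 5.5, 8.0, 15.0, 40.0, 80.0])))
        t = ends[-1] + gap
    return np.array(starts), np.array(ends), np.array(depths)
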