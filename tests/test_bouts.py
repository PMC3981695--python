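"""Sequential bout detection: test statistic, partition oracle, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divebout.bouts import (
    BoutConfig,
    bout_table,
    detect_bouts,
    fraction_outside_bouts,
    summarize_bout,
)
from divebout.synth import (
    BoutGenParams,
    generate_trace,
    sample_bout_metrics,
)

from conftest import square_dive_df
from _oracles import detect_bouts_oracle, random_dive_sequence


def _df_from_intervals(intervals, depth=10.0, duration=100.0):
    """Dives at unit duration separated by the given surface intervals."""
    starts, t = [], 0.0
    for g in [0.0] + list(intervals):
        t += g
        starts.append(t)
        t += duration
    return pd.DataFrame(
        {
            "animal_id": "A",
            "start_s": starts,
            "end_s": [s + duration for s in starts],
            "max_depth": depth,
            "duration": duration,
            "bottom_time": duration / 2,
            "shape_class": "square",
        }
    )


def test_hugely_long_interval_closes_bout():
    # history [50, 60, 70]: t = (1000-60)/(10*sqrt(4/3)) ~ 81.4 >> t_0.95(2)
    t_stat = (1000 - 60) / (10.0 * np.sqrt(1 + 1 / 3))
    assert t_stat == pytest.approx(81.4, abs=0.1)
    assert t_stat > stats.t.ppf(0.95, 2)
    df = _df_from_intervals([50, 60, 70, 1000, 50, 60, 70])
    bouts, unassigned = detect_bouts(df)
    assert bouts[0].n_dives == 4
    assert len(bouts) == 2 and not unassigned


def test_interval_equal_to_running_mean_joins():
    df = _df_from_intervals([50, 60, 70, 60.0])
    bouts, _ = detect_bouts(df)
    assert bouts[0].n_dives == 5


def test_zero_variance_history_sign_rule():
    joins = _df_from_intervals([60, 60, 60, 60.0])
    assert detect_bouts(joins)[0][0].n_dives == 5
    closes = _df_from_intervals([60, 60, 60, 60.0001])
    assert detect_bouts(closes)[0][0].n_dives == 4


def test_three_qualifying_dives_do_not_start_a_bout():
    df = _df_from_intervals([50, 60], depth=10.0)
    bouts, unassigned = detect_bouts(df)
    assert bouts == []
    assert unassigned == [0, 1, 2]


def test_shallow_dives_cannot_seed():
    df = _df_from_intervals([50, 60, 70, 55, 65], depth=5.5)
    bouts, unassigned = detect_bouts(df)
    assert bouts == [] and len(unassigned) == 6


def test_homogeneous_bout_summary():
    df = square_dive_df(n=4, depth=40.0, duration=300.0, bottom=180.0,
                        interval=60.0)
    b = summarize_bout(df)
    assert b.n_dives == 4
    assert b.mean_depth == 40.0
    assert b.pct_square == 1.0 and b.pct_v == 0.0
    assert b.bout_duration == 3 * 360.0 + 300.0
    assert b.pct_time_at_depth == pytest.approx(4 * 180.0 / b.bout_duration)


def test_mixed_shape_fractions():
    df = square_dive_df(n=5)
    df.loc[3:, "shape_class"] = "V"
    b = summarize_bout(df)
    assert b.pct_square == pytest.approx(0.6)
    assert b.pct_v == pytest.approx(0.4)


def test_type_i_bout_duration_matches_published_summary():
    df = sample_bout_metrics(n=200, seed=4, weights=[1, 0, 0])
    se = df.bout_duration.std() / np.sqrt(len(df))
    assert abs(df.bout_duration.mean() - 2267.70) < 3 * se


@pytest.mark.parametrize("seed", range(12))
def test_partition_equals_bruteforce_reference(seed):
    rng = np.random.default_rng(seed)
    starts, ends, depths = random_dive_sequence(rng, int(rng.integers(20, 120)))
    df = pd.DataFrame(
        {"animal_id": "A", "start_s": starts, "end_s": ends,
         "max_depth": depths, "duration": ends - starts,
         "bottom_time": (ends - starts) / 2, "shape_class": "square"}
    )
    bouts, unassigned = detect_bouts(df)
    ref_bouts, ref_un = detect_bouts_oracle(
        list(starts), list(ends), list(depths)
    )
    assert [b.dive_indices for b in bouts] == ref_bouts
    assert unassigned == ref_un


def test_in_bout_dive_count_non_increasing_in_alpha():
    rng = np.random.default_rng(77)
    starts, ends, depths = random_dive_sequence(rng, 150)
    df = pd.DataFrame(
        {"animal_id": "A", "start_s": starts, "end_s": ends,
         "max_depth": depths, "duration": ends - starts,
         "bottom_time": (ends - starts) / 2, "shape_class": "square"}
    )
    counts = []
    for alpha in (0.001, 0.01, 0.05, 0.2, 0.5):
        bouts, _ = detect_bouts(df, BoutConfig(alpha=alpha))
        counts.append(sum(b.n_dives for b in bouts))
    assert counts == sorted(counts, reverse=True)


def test_partition_invariant_to_time_translation():
    rng = np.random.default_rng(5)
    starts, ends, depths = random_dive_sequence(rng, 80)
    def run(shift):
        df = pd.DataFrame(
            {"animal_id": "A", "start_s": starts + shift,
             "end_s": ends + shift, "max_depth": depths,
             "duration": ends - starts, "bottom_time": (ends - starts) / 2,
             "shape_class": "square"}
        )
        bouts, un = detect_bouts(df)
        return [b.dive_indices for b in bouts], un
    assert run(0.0) == run(86_400.0)


def test_fraction_outside_trivial_cases():
    df = _df_from_intervals([50, 60, 70, 55])
    bouts, _ = detect_bouts(df)
    assert fraction_outside_bouts(df, bouts) == 0.0
    lone = _df_from_intervals([50], depth=10.0)
    assert fraction_outside_bouts(lone, []) == 1.0
    with pytest.raises(ValueError):
        fraction_outside_bouts(df.iloc[:0], [])


def test_isolated_dive_fraction_recovered():
    from divebout.dives import dive_table
    from divebout.trace import detect_dives

    bp = BoutGenParams(isolated_fraction=0.10)
    trace, truth = generate_trace(bout_params=bp, n_bouts=80, seed=3)
    df = dive_table(trace, detect_dives(trace))
    bouts, _ = detect_bouts(df)
    frac = fraction_outside_bouts(df, bouts)
    true_frac = (truth[truth.detectable].bout_id < 0).mean()
    se = np.sqrt(true_frac * (1 - true_frac) / len(df))
    assert abs(frac - true_frac) < 3 * se


def test_bout_covariates_by_majority():
    df = square_dive_df(n=5)
    df["light"] = ["day", "day", "night", "day", "night"]
    b = summarize_bout(df)
    assert b.covariates["light"] == "day"
    df["light"] = ["night", "day", "night", "day", "day"]
    df = df.iloc[:4]
    b = summarize_bout(df)  # 2-2 tie -> first dive's value
    assert b.covariates["light"] == "night"


def test_bout_table_schema():
    df = square_dive_df(n=4)
    bouts, _ = detect_bouts(df)
    table = bout_table(bouts)
    for col in ("n_dives", "mean_depth", "mean_duration",
                "mean_surface_interval", "bout_duration",
                "pct_time_at_depth", "pct_square", "pct_v"):
        assert col in table.columns
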