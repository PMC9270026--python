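"""Heatmap interpolation, matched time points, and hypothesis tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flysleep import (
    baseline_heatmap,
    baseline_sleep_profile,
    gain_trend,
    group_comparison,
    match_morning_evening,
    paired_comparison,
    rebound_heatmap,
    score_sleep,
)

from conftest import make_table


def test_full_protocol_heatmap_has_no_interpolated_rows(gain_cohort, full_schedule):
    _, _, series = gain_cohort
    hm = rebound_heatmap(series, full_schedule)
    assert hm.values.shape == (24, 9)
    assert hm.observed_mask.all()
    assert np.all((hm.values >= 0) & (hm.values <= 30))


def test_abridged_heatmap_interpolates_missing_rows(small_cohort, abridged_schedule):
    _, _, series = small_cohort
    hm = rebound_heatmap(series, abridged_schedule)
    assert hm.values.shape == (24, 9)
    assert hm.observed_mask.sum() == 5
    assert set(hm.rows_zt[hm.observed_mask]) == {1.5, 2.5, 8.5, 9.5, 10.5}


def test_observed_rows_untouched_by_interpolation(small_cohort, abridged_schedule):
    _, _, series = small_cohort
    hm = rebound_heatmap(series, abridged_schedule)
    direct = {}
    for e in abridged_schedule.episodes:
        start, end = e.rebound_window
        w = series.asleep[:, start:end].reshape(series.n_flies, 9, 30).sum(axis=2)
        direct[e.onset_zt] = w.mean(axis=0)
    for zt, vals in direct.items():
        row = hm.values[hm.rows_zt == zt][0]
        assert np.allclose(row, vals)


def test_midpoint_interpolation_between_two_rows():
    counts = np.ones((2, 6 * 1440), dtype=int)
    series = score_sleep(make_table(counts))
    # hand-build two episodes whose onsets sit 2 h apart on the clock
    from flysleep import Episode, SSDSchedule

    e0 = Episode(0, 1440, 1590, 1860, onset_zt=2.5)        # day 1
    e1 = Episode(1, 3000, 3150, 3420, onset_zt=4.5)        # day 2
    # constant sleep levels: 10 of 30 min per bin after e0, 20 after e1
    series.asleep[:, :] = False
    series.asleep[:, 1590:1860] = np.tile(
        np.r_[np.ones(10, bool), np.zeros(20, bool)], 9
    )
    series.asleep[:, 3150:3420] = np.tile(
        np.r_[np.ones(20, bool), np.zeros(10, bool)], 9
    )
    sched = SSDSchedule(episodes=[e0, e1], baseline_days=[0], mode="abridged")
    hm = rebound_heatmap(series, sched, row_grid=np.array([2.5, 3.5, 4.5]))
    mid = hm.values[hm.rows_zt == 3.5][0]
    assert np.allclose(mid, 15.0)


def test_heatmap_circular_wrap_uses_both_neighbors():
    from flysleep import Episode, SSDSchedule

    counts = np.ones((1, 5 * 1440), dtype=int)
    series = score_sleep(make_table(counts))
    e0 = Episode(0, 1440, 1590, 1860, onset_zt=23.0)
    e1 = Episode(1, 2880, 3030, 3300, onset_zt=3.0)
    series.asleep[:, 1590:1860] = True   # 30 per bin at ZT23
    series.asleep[:, 3030:3300] = False  # 0 per bin at ZT3
    sched = SSDSchedule(episodes=[e0, e1], baseline_days=[0], mode="abridged")
    hm = rebound_heatmap(series, sched, row_grid=np.array([1.0, 3.0, 23.0]))
    row = hm.values[hm.rows_zt == 1.0][0]  # ZT1 sits midway on the circle
    assert np.allclose(row, 15.0)


def test_baseline_heatmap_delegates_to_profile(small_cohort):
    _, _, series = small_cohort
    a = baseline_heatmap(series, [1, 2]).values
    b = baseline_sleep_profile(series, [1, 2]).values
    assert np.array_equal(a, b)


def _summaries(rows):
    return pd.DataFrame(rows, columns=["onset_zt", "mean_baseline_rebound", "mean_lost"])


def brute_force_match(df, tol_b, tol_l):
    m = df[(df.onset_zt >= 0) & (df.onset_zt < 6)]
    e = df[(df.onset_zt >= 6) & (df.onset_zt < 12)]
    cand = pd.concat([m, e])
    sd_b = cand.mean_baseline_rebound.std(ddof=0) or 1.0
    sd_l = cand.mean_lost.std(ddof=0) or 1.0
    best, key = None, None
    for (_, rm), (_, re_) in itertools.product(m.iterrows(), e.iterrows()):
        db = abs(rm.mean_baseline_rebound - re_.mean_baseline_rebound)
        dl = abs(rm.mean_lost - re_.mean_lost)
        if db > tol_b or dl > tol_l:
            continue
        k = (db / sd_b + dl / sd_l, db, rm.onset_zt)
        if key is None or k < key:
            best, key = (rm.onset_zt, re_.onset_zt), k
    return best


def test_match_single_admissible_pair():
    df = _summaries([(1.5, 100, 90), (9.5, 105, 92)])
    pair = match_morning_evening(df)
    assert pair.found and (pair.morning_zt, pair.evening_zt) == (1.5, 9.5)


def test_match_prefers_exactly_equal_baseline():
    df = _summaries([(2.5, 100, 90), (8.5, 100, 90), (9.5, 101, 90)])
    pair = match_morning_evening(df)
    assert (pair.morning_zt, pair.evening_zt) == (2.5, 8.5)
    assert pair.delta_baseline == 0


def test_match_reports_no_match_within_tolerances():
    df = _summaries([(1.5, 100, 90), (9.5, 300, 90)])
    pair = match_morning_evening(df, tol_baseline=30)
    assert not pair.found and "tolerance" in pair.reason


@settings(derandomize=True, max_examples=40, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_match_equals_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    zts = np.concatenate([rng.uniform(0, 6, 4), rng.uniform(6, 12, 4)])
    df = _summaries(
        [(z, rng.uniform(50, 150), rng.uniform(60, 120)) for z in np.round(zts, 2)]
    )
    pair = match_morning_evening(df)
    brute = brute_force_match(df, 45.0, 45.0)
    if brute is None:
        assert not pair.found
    else:
        assert (pair.morning_zt, pair.evening_zt) == brute


def test_paired_t_against_hand_computation():
    x = np.array([5.0, 7.0, 9.0, 6.0])
    y = np.array([3.0, 4.0, 8.0, 2.0])
    d = x - y
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(4))
    res = paired_comparison(x, y)
    assert res.statistic == pytest.approx(t_hand)
    assert res.df == 3
    assert not res.degenerate


def test_paired_t_degenerate_flags():
    res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.degenerate  # zero differences
    res = paired_comparison([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
    assert res.degenerate  # constant nonzero differences
    res = paired_comparison([1.0], [2.0])
    assert res.degenerate and res.n == 1


def test_anova_identical_groups_flat():
    g = {"a": np.array([1.0, 1.0, 1.0]), "b": np.array([1.0, 1.0, 1.0])}
    res = group_comparison(g)
    assert res.degenerate and res.F == 0.0
    assert np.all(res.pairwise["p_adj"] >= 0.99)


def test_anova_two_groups_is_t_squared():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
    res = group_comparison({"a": a, "b": b})
    from scipy.stats import ttest_ind

    t, _ = ttest_ind(a, b)
    assert res.F == pytest.approx(t**2)


def test_anova_three_groups_hand_decomposition():
    groups = {"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0]), "c": np.array([5.0, 6.0])}
    allv = np.concatenate(list(groups.values()))
    ss_between = sum(len(v) * (v.mean() - allv.mean()) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    F_hand = (ss_between / 2) / (ss_within / 3)
    res = group_comparison(groups)
    assert res.F == pytest.approx(F_hand)
    assert res.df_between == 2 and res.df_within == 3
    assert len(res.pairwise) == 3


def test_gain_trend_exact_lines():
    flat = gain_trend(np.full(6, 42.0))
    assert flat.slope == pytest.approx(0.0)
    line = gain_trend(np.array([0.0, 1.0, 2.0, 3.0]))
    assert line.slope == pytest.approx(1.0)
    with pytest.raises(ValueError):
        gain_trend(np.array([1.0, 2.0]))
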