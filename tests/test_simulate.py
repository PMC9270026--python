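"""Synthetic cohort generator: determinism, forced wake, gain injection."""

import numpy as np
import pytest

from flysleep import (
    SimConfig,
    SimConfigError,
    circadian_sleep_fraction,
    cohort_metrics,
    expected_baseline_sleep,
    gain_profile,
    inject_rebound_gain,
    make_full_ssd,
    score_sleep,
    simulate_cohort,
    sleep_in_window,
)
from flysleep.scoring import _runs
from flysleep.simulate import window_sleep_samples


def test_same_seed_reproduces_table(abridged_schedule):
    cfg = SimConfig(n_flies=4, seed=3)
    a = simulate_cohort(cfg, abridged_schedule)
    b = simulate_cohort(SimConfig(n_flies=4, seed=3), abridged_schedule)
    assert a.equals(b)


def test_growing_cohort_preserves_existing_flies(abridged_schedule):
    small = simulate_cohort(SimConfig(n_flies=3, seed=5), abridged_schedule)
    large = simulate_cohort(SimConfig(n_flies=6, seed=5), abridged_schedule)
    assert np.array_equal(large.counts[:3], small.counts)


def test_wake_minutes_always_emit_counts():
    """Zero counts only ever come from simulated sleep, so scored wake has
    counts >= 1 (a final sleep bout truncated below 5 min is the one
    scored-awake zero-count case and sits at the recording edge)."""
    cfg = SimConfig(n_flies=4, seed=1)
    table = simulate_cohort(cfg, None, n_days=2)
    series = score_sleep(table)
    for i in range(table.n_flies):
        starts, lengths = _runs(table.counts[i] == 0)
        trailing = (
            len(starts) and starts[-1] + lengths[-1] == table.n_minutes
            and lengths[-1] < 5
        )
        end = starts[-1] if trailing else table.n_minutes
        awake = ~series.asleep[i, :end]
        assert np.all(table.counts[i, :end][awake] >= 1)


def test_scored_sleep_equals_simulated_inactivity():
    """The 5-min bout floor makes scoring lossless on undisturbed data:
    every maximal zero run (except a possible truncated final one) is >= 5."""
    table = simulate_cohort(SimConfig(n_flies=6, seed=2), None, n_days=2)
    for i in range(table.n_flies):
        starts, lengths = _runs(table.counts[i] == 0)
        interior = lengths[:-1] if len(lengths) and starts[-1] + lengths[-1] == table.n_minutes else lengths
        assert np.all(interior >= 5)
    series = score_sleep(table)
    inactive = (table.counts == 0).sum(axis=1)
    assert np.all(inactive - series.total_sleep() <= 4)


def test_full_eta_forces_zero_sd_sleep(abridged_schedule):
    cfg = SimConfig(n_flies=6, seed=4, eta=1.0)
    series = score_sleep(simulate_cohort(cfg, abridged_schedule))
    for e in abridged_schedule.episodes:
        assert np.all(sleep_in_window(series, e.sd_start_t, e.sd_end_t) == 0)


def test_sleep_dominant_limit_approaches_full_day():
    cfg = SimConfig(
        n_flies=4, seed=6, f_mid=0.95, f_amp=0.0,
        dip_morning_depth=0.0, dip_evening_depth=0.0, f_ceil=0.99,
    )
    table = simulate_cohort(cfg, None, n_days=2)
    daily = score_sleep(table).total_sleep() / 2
    assert np.all(daily > 1300)  # ~the full 1440 min


def test_circadian_fraction_shape():
    cfg = SimConfig()
    zt = np.arange(0, 24, 0.25)
    f = circadian_sleep_fraction(cfg, zt)
    assert np.all((f >= cfg.f_floor) & (f <= cfg.f_ceil))
    # wake peaks (propensity dips) around lights-on and lights-off
    assert f[zt == 1.0][0] < f[zt == 6.0][0]
    assert f[zt == 11.0][0] < f[zt == 6.0][0]
    # consolidated night sleep
    assert f[zt == 18.0][0] > 0.7


def test_expected_baseline_sleep_limits():
    awake_cfg = SimConfig(
        seed=1, f_mid=0.05, f_amp=0.0, dip_morning_depth=0.0,
        dip_evening_depth=0.0, f_floor=0.01,
    )
    assert expected_baseline_sleep(awake_cfg, 2.0, 270) < 40
    sleepy_cfg = SimConfig(
        seed=1, f_mid=0.95, f_amp=0.0, dip_morning_depth=0.0,
        dip_evening_depth=0.0, f_ceil=0.99,
    )
    assert expected_baseline_sleep(sleepy_cfg, 2.0, 270) > 240


def test_balanced_process_sleeps_half_the_window():
    cfg = SimConfig(
        seed=8, f_mid=0.5, f_amp=0.0, dip_morning_depth=0.0, dip_evening_depth=0.0
    )
    est = expected_baseline_sleep(cfg, 6.0, 270)
    assert est == pytest.approx(135.0, abs=8.0)


def test_gain_profile_hits_anchors_and_interpolates():
    cfg = SimConfig(mode="gain_injection")
    assert gain_profile(cfg, 1.5) == pytest.approx(133.0)
    assert gain_profile(cfg, 9.5) == pytest.approx(51.0)
    mid = gain_profile(cfg, 5.5 + 2.0)  # between the 5.5 and 9.5 anchors
    assert gain_profile(cfg, 5.5) > mid > gain_profile(cfg, 9.5)


def test_injection_requires_feasible_gain(full_schedule):
    cfg = SimConfig(mode="gain_injection", gain_anchors={0.0: 400.0})
    with pytest.raises(SimConfigError):
        simulate_cohort(cfg, full_schedule)


def test_injection_saturation_fills_the_window():
    cfg = SimConfig(n_flies=4, seed=9, mode="gain_injection")
    sched = make_full_ssd(n_episodes=1)
    e = sched.episodes[0]
    B = expected_baseline_sleep(cfg, e.onset_zt, 270)
    cfg.gain_anchors = {e.onset_zt: 0.95 * 270 - B}  # near-saturating gain
    series = score_sleep(simulate_cohort(cfg, sched))
    reb = sleep_in_window(series, e.sd_end_t, e.rebound_end_t)
    assert np.all(reb > 0.85 * 270)


def test_null_injection_measures_zero_gain(full_schedule):
    """g = 0 everywhere: the measured cohort mean gain hovers near zero."""
    cfg = SimConfig(n_flies=32, seed=10, mode="gain_injection",
                    gain_anchors={0.0: 0.0})
    series = score_sleep(simulate_cohort(cfg, full_schedule))
    metrics = cohort_metrics(series, full_schedule)
    grand = metrics.groupby("episode_index")["sleep_gain"].mean()
    sem = metrics.groupby("episode_index")["sleep_gain"].sem()
    assert abs(grand.mean()) < 6.0
    assert np.sum(np.abs(grand) <= 3 * sem) >= 22  # ~all episodes within 3 SEM


def test_injected_gain_recovered_at_n100():
    """Monte-Carlo recovery: injected g=100 at one ZT, n=100 flies."""
    sched = make_full_ssd(n_episodes=1)  # onset ZT4.5
    cfg = SimConfig(n_flies=100, seed=11, mode="gain_injection",
                    gain_anchors={4.5: 100.0})
    series = score_sleep(simulate_cohort(cfg, sched))
    metrics = cohort_metrics(series, sched)
    gains = metrics["sleep_gain"]
    sem = gains.sem()
    assert abs(gains.mean() - 100.0) <= 3 * sem


def test_window_sampler_tracks_target_fraction():
    cfg = SimConfig(seed=12)
    rng = np.random.default_rng(0)
    samples = window_sleep_samples(np.array([0.3, 0.7]), cfg, 270, 400, rng)
    means = samples.mean(axis=1)
    assert means[1] > means[0]
    assert means[0] == pytest.approx(0.3 * 270, rel=0.25)


def test_efficiency_concentration_under_strong_and_weak_stimulation(full_schedule):
    from flysleep import apply_efficiency_filter

    strong = SimConfig(n_flies=10, seed=13, eta=0.99)
    metrics = cohort_metrics(score_sleep(simulate_cohort(strong, full_schedule)), full_schedule)
    res = apply_efficiency_filter(metrics)
    assert len(res.retained) >= 8  # strong stimulation retains most flies

    weak = SimConfig(n_flies=10, seed=13, eta=0.5)
    metrics = cohort_metrics(score_sleep(simulate_cohort(weak, full_schedule)), full_schedule)
    res = apply_efficiency_filter(metrics)
    assert len(res.retained) <= 2  # weak stimulation fails the >90% rule


def test_config_invariants_enforced():
    with pytest.raises(SimConfigError):
        SimConfig(eta=1.5)
    with pytest.raises(SimConfigError):
        SimConfig(min_sleep_bout=3)
    with pytest.raises(SimConfigError):
        SimConfig(mode="nope")
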