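"""Per-fly, per-episode sleep-homeostasis metrics.

For each deprivation episode and fly:

* ``sleep_lost``  = baseline sleep in the SD clock window − sleep during SD,
* ``sleep_gain``  = rebound sleep − baseline sleep in the equivalent
  4.5 h clock window,
* ``efficiency``  = sleep_lost / baseline SD-window sleep (fraction of
  baseline sleep removed by the stimulus),
* ``latency``     = minutes from SD end to the first rebound sleep.

Baseline terms are means over the configured baseline days at matching
clock windows.  Windows are mapped by zeitgeber time and wrap circularly
within each baseline day, so a deprivation straddling midnight compares
against the same clock span of the baseline day rather than bleeding
into protocol days.

The inclusion filter retains a fly only if its efficiency exceeds the
threshold (default 0.9, i.e. >90% of baseline sleep removed) at every
episode where baseline SD-window sleep is positive; episodes with zero
baseline sleep cannot constrain efficiency and are logged as vacuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dam import MINUTES_PER_DAY
from .schedule import Episode, SSDSchedule
from .scoring import SleepSeries, sleep_in_window, sleep_latency

METRIC_COLUMNS = [
    "fly_id",
    "episode_index",
    "onset_zt",
    "baseline_sleep_sd_window",
    "sd_sleep",
    "sleep_lost",
    "baseline_sleep_rebound_window",
    "rebound_sleep",
    "sleep_gain",
    "efficiency",
    "latency",
    "latency_censored",
]


def clock_window_indices(
    day: int, start_zt: float, length_min: int, zt0: float = 0.0
) -> np.ndarray:
    """Minute indices of a clock window mapped onto one experiment day.

    The window starts at ``start_zt`` on ``day`` and wraps circularly
    within that day if it crosses the day boundary.
    """
    day_start = day * MINUTES_PER_DAY
    offset = int(round(((start_zt - zt0) % 24.0) * 60))
    return day_start + (offset + np.arange(length_min)) % MINUTES_PER_DAY


def baseline_window_sleep(
    series: SleepSeries,
    baseline_days: list[int],
    start_zt: float,
    length_min: int,
) -> np.ndarray:
    """Mean scored sleep per fly over baseline days at a clock window."""
    if not baseline_days:
        raise ValueError("no baseline days configured")
    per_day = []
    for d in baseline_days:
        idx = clock_window_indices(d, start_zt, length_min, series.zt0)
        if idx.max() >= series.n_minutes:
            raise ValueError(f"baseline day {d} not covered by the series")
        per_day.append(series.asleep[:, idx].sum(axis=1))
    return np.mean(per_day, axis=0)


def episode_metrics(
    series: SleepSeries, schedule: SSDSchedule, episode: Episode
) -> pd.DataFrame:
    """Metrics for every fly at one episode (one row per fly)."""
    if episode.rebound_end_t > series.n_minutes:
        raise ValueError(
            f"episode {episode.index} extends to minute {episode.rebound_end_t}, "
            f"beyond the {series.n_minutes}-min recording"
        )
    sd_start, sd_end = episode.sd_window
    reb_start, reb_end = episode.rebound_window
    sd_len = sd_end - sd_start
    reb_len = reb_end - reb_start
    sd_start_zt = float(series.zt[sd_start])
    onset_zt = float(series.zt[sd_end])

    base_sd = baseline_window_sleep(series, schedule.baseline_days, sd_start_zt, sd_len)
    base_reb = baseline_window_sleep(series, schedule.baseline_days, onset_zt, reb_len)
    sd_sleep = sleep_in_window(series, sd_start, sd_end).astype(float)
    reb_sleep = sleep_in_window(series, reb_start, reb_end).astype(float)
    latency, censored = sleep_latency(series, reb_start, reb_end)

    sleep_lost = base_sd - sd_sleep
    sleep_gain = reb_sleep - base_reb
    with np.errstate(divide="ignore", invalid="ignore"):
        efficiency = np.where(base_sd > 0, sleep_lost / base_sd, np.nan)

    return pd.DataFrame(
        {
            "fly_id": series.fly_ids,
            "episode_index": episode.index,
            "onset_zt": onset_zt,
            "baseline_sleep_sd_window": base_sd,
            "sd_sleep": sd_sleep,
            "sleep_lost": sleep_lost,
            "baseline_sleep_rebound_window": base_reb,
            "rebound_sleep": reb_sleep,
            "sleep_gain": sleep_gain,
            "efficiency": efficiency,
            "latency": latency,
            "latency_censored": censored,
        }
    )


def cohort_metrics(series: SleepSeries, schedule: SSDSchedule) -> pd.DataFrame:
    """Metrics for every fly × episode, concatenated."""
    frames = [episode_metrics(series, schedule, e) for e in schedule.episodes]
    return pd.concat(frames, ignore_index=True)[METRIC_COLUMNS]


@dataclass
class FilterResult:
    retained: list[str]
    excluded: list[str]
    failures: pd.DataFrame       # fly_id, episode_index, efficiency
    vacuous: pd.DataFrame        # episodes with zero baseline SD-window sleep


def apply_efficiency_filter(
    metrics: pd.DataFrame, threshold: float = 0.9, per: str = "fly"
) -> FilterResult:
    """Apply the >threshold deprivation-efficiency inclusion rule.

    ``per="fly"`` (default): a fly is retained iff efficiency > threshold
    at every constrained episode.  ``per="episode"``: individual fly ×
    episode records failing the rule are dropped instead of whole flies.
    """
    if per not in ("fly", "episode"):
        raise ValueError("per must be 'fly' or 'episode'")
    constrained = metrics[metrics["baseline_sleep_sd_window"] > 0]
    vacuous = metrics[metrics["baseline_sleep_sd_window"] <= 0][
        ["fly_id", "episode_index"]
    ].reset_index(drop=True)
    failing = constrained[constrained["efficiency"] <= threshold][
        ["fly_id", "episode_index", "efficiency"]
    ].reset_index(drop=True)
    all_ids = list(dict.fromkeys(metrics["fly_id"]))
    bad = set(failing["fly_id"])
    if per == "fly":
        retained = [f for f in all_ids if f not in bad]
        excluded = [f for f in all_ids if f in bad]
    else:
        retained = all_ids
        excluded = []
    return FilterResult(retained=retained, excluded=excluded, failures=failing, vacuous=vacuous)


def percent_recovered(metrics: pd.DataFrame) -> pd.Series:
    """100 × sleep_gain / sleep_lost; NaN (flagged undefined) when no sleep was lost."""
    lost = metrics["sleep_lost"].to_numpy(dtype=float)
    gain = metrics["sleep_gain"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(lost > 0, 100.0 * gain / lost, np.nan)
    return pd.Series(pct, index=metrics.index, name="percent_recovered")


def cohort_summary(
    metrics: pd.DataFrame,
    onset_zt: float,
    metric: str = "sleep_gain",
    retained: list[str] | None = None,
) -> dict:
    """Mean ± SEM of one metric over (retained) flies at one rebound onset."""
    sel = metrics[np.isclose(metrics["onset_zt"], onset_zt)]
    if retained is not None:
        sel = sel[sel["fly_id"].isin(retained)]
    values = sel[metric].to_numpy(dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    if n == 0:
        raise ValueError(f"no flies with {metric} at onset ZT{onset_zt}")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {"mean": mean, "sem": sem, "n": n}
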