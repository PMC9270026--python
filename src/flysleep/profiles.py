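"""Daily activity/sleep profiles and anticipation indices.

An *eduction* is a daily profile: counts (or sleep minutes) summed in
fixed clock bins and averaged across flies and days.  The anticipation
index quantifies clock-driven ramping of activity before a light
transition as a normalized contrast

    AI = (A_near − A_far) / (A_near + A_far)

where ``A_near`` is summed activity in the 3 h immediately preceding the
transition and ``A_far`` the 3 h before that.  The same mirrored formula
serves lights-on (morning, ZT24→0) and lights-off (evening, ZT12).  The
index is dimensionless in [−1, 1] and invariant to uniform scaling of
activity; it is undefined (NaN) when both window sums are zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dam import ActivityTable, MINUTES_PER_DAY
from .scoring import SleepSeries


@dataclass
class DailyProfile:
    """Mean activity (or sleep minutes) per clock bin over stated days."""

    bin_minutes: int
    values: np.ndarray  # length 1440 / bin_minutes; bin b covers ZT [b*bin, (b+1)*bin) minutes
    n_days: int
    n_flies: int
    kind: str = "activity"  # or "sleep"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_bins * self.bin_minutes != MINUTES_PER_DAY:
            raise ValueError("bins must tile the 24 h day")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def bin_zts(self) -> np.ndarray:
        """ZT (hours) at which each bin starts."""
        return np.arange(self.n_bins) * self.bin_minutes / 60.0

    @property
    def total(self) -> float:
        """Daily total (counts or sleep minutes per 24 h)."""
        return float(self.values.sum())


@dataclass(frozen=True)
class AnticipationIndex:
    transition: str  # "lights_on" | "lights_off"
    value: float     # dimensionless in [-1, 1]; NaN when undefined


def _per_fly_day_bins(
    data: np.ndarray, t: np.ndarray, zt0: float, days: list[int], bin_minutes: int
) -> np.ndarray:
    """Sum ``data`` (n_flies, T) into clock bins -> (n_flies, n_days, n_bins)."""
    if MINUTES_PER_DAY % bin_minutes:
        raise ValueError("bin_minutes must divide 1440")
    n_bins = MINUTES_PER_DAY // bin_minutes
    clock_min = (int(round(zt0 * 60)) + t) % MINUTES_PER_DAY
    bin_idx = clock_min // bin_minutes
    day_idx = t // MINUTES_PER_DAY
    out = np.zeros((data.shape[0], len(days), n_bins))
    for j, d in enumerate(days):
        sel = day_idx == d
        if not np.any(sel):
            raise ValueError(f"day {d} absent from the recording")
        if sel.sum() != MINUTES_PER_DAY:
            raise ValueError(f"day {d} is incomplete ({int(sel.sum())} min)")
        b = bin_idx[sel]
        for i in range(data.shape[0]):
            out[i, j] = np.bincount(b, weights=data[i, sel], minlength=n_bins)
    return out


def eduction(
    table: ActivityTable, days: list[int], bin_minutes: int = 30
) -> DailyProfile:
    """Averaged daily activity profile over the given days and all flies."""
    binned = _per_fly_day_bins(
        table.counts.astype(float), table.t, table.zt0, list(days), bin_minutes
    )
    return DailyProfile(
        bin_minutes=bin_minutes,
        values=binned.mean(axis=(0, 1)),
        n_days=len(days),
        n_flies=table.n_flies,
        kind="activity",
    )


def baseline_sleep_profile(
    series: SleepSeries, baseline_days: list[int], bin_minutes: int = 30
) -> DailyProfile:
    """Mean sleep minutes per clock bin over the baseline days.

    ``profile.total`` is the mean daily sleep (minutes per 24 h).
    """
    binned = _per_fly_day_bins(
        series.asleep.astype(float), series.t, series.zt0, list(baseline_days), bin_minutes
    )
    return DailyProfile(
        bin_minutes=bin_minutes,
        values=binned.mean(axis=(0, 1)),
        n_days=len(baseline_days),
        n_flies=series.n_flies,
        kind="sleep",
    )


def anticipation_index(
    profile: DailyProfile,
    transition: str,
    near_hours: float = 3.0,
    far_hours: float = 3.0,
) -> AnticipationIndex:
    """Normalized near-vs-far pre-transition activity contrast."""
    if transition == "lights_on":
        tr_zt = 24.0
    elif transition == "lights_off":
        tr_zt = 12.0
    else:
        raise ValueError("transition must be 'lights_on' or 'lights_off'")
    span_min = (near_hours + far_hours) * 60.0
    if span_min > MINUTES_PER_DAY:
        raise ValueError("anticipation windows exceed 24 h")
    bw = profile.bin_minutes
    for hours in (near_hours, far_hours):
        if (hours * 60) % bw:
            raise ValueError("window lengths must be whole numbers of bins")

    def window_sum(start_zt: float, hours: float) -> float:
        n = int(hours * 60) // bw
        b0 = int(round((start_zt % 24.0) * 60)) // bw
        idx = (b0 + np.arange(n)) % profile.n_bins
        return float(profile.values[idx].sum())

    near = window_sum(tr_zt - near_hours, near_hours)
    far = window_sum(tr_zt - near_hours - far_hours, far_hours)
    denom = near + far
    value = (near - far) / denom if denom > 0 else float("nan")
    return AnticipationIndex(transition=transition, value=value)
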