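"""Scheduled-sleep-deprivation (SSD) protocols.

The full ultradian protocol applies a 2.5 h mechanical deprivation (SD)
followed by 4.5 h of rebound, repeating every 7 h for 24 episodes.
Because gcd(7, 24) = 1, the rebound onset sweeps every one-hour residue
class of the 24 h day over 7 days.  The abridged protocol applies the
same 2.5 h stimulus five times — ZT0, ZT8 and ZT23 of day 3, ZT7 of day
4 and ZT6 of day 5 — giving rebound onsets {2.5, 10.5, 1.5, 9.5, 8.5}.

Time is a 0-based minute grid; windows are half-open [start, end).
``zt0_minute`` is the minute index at which ZT0 of the first deprivation
day falls (default: day 3 of a recording that starts at lights-on, after
one acclimation day and two full baseline days).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dam import ActivityTable, MINUTES_PER_DAY

SD_MINUTES = 150        # 2.5 h of stimulation
REBOUND_MINUTES = 270   # 4.5 h of recovery opportunity
EPISODE_SPAN = SD_MINUTES + REBOUND_MINUTES  # 420 min = 7 h: tiles time
DEFAULT_ZT0_MINUTE = 3 * MINUTES_PER_DAY
DEFAULT_BASELINE_DAYS = (1, 2)

# Day/ZT positions of the five abridged stimulations, relative to the
# first deprivation day.
ABRIDGED_SD_STARTS = ((0, 0.0), (0, 8.0), (0, 23.0), (1, 7.0), (2, 6.0))


@dataclass(frozen=True)
class Episode:
    """One SD + rebound cycle; ``onset_zt`` is the ZT at which rebound begins."""

    index: int
    sd_start_t: int
    sd_end_t: int
    rebound_end_t: int
    onset_zt: float

    @property
    def sd_window(self) -> tuple[int, int]:
        return (self.sd_start_t, self.sd_end_t)

    @property
    def rebound_window(self) -> tuple[int, int]:
        return (self.sd_end_t, self.rebound_end_t)


@dataclass
class SSDSchedule:
    episodes: list[Episode]
    baseline_days: list[int] = field(default_factory=lambda: list(DEFAULT_BASELINE_DAYS))
    mode: str = "full"
    zt0: float = 0.0  # zeitgeber time of minute 0 of the recording

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def onset_zts(self) -> list[float]:
        return [e.onset_zt for e in self.episodes]

    @property
    def end_t(self) -> int:
        return max(e.rebound_end_t for e in self.episodes)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode": self.mode,
            "zt0": self.zt0,
            "baseline_days": list(self.baseline_days),
            "episodes": [
                {
                    "index": e.index,
                    "sd_start_t": e.sd_start_t,
                    "sd_end_t": e.sd_end_t,
                    "rebound_end_t": e.rebound_end_t,
                    "onset_zt": e.onset_zt,
                }
                for e in self.episodes
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SSDSchedule":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if "{" not in text:  # a path, not inline JSON
                text = Path(text).read_text()
        payload = json.loads(text)
        episodes = [Episode(**e) for e in payload["episodes"]]
        return cls(
            episodes=episodes,
            baseline_days=list(payload.get("baseline_days", DEFAULT_BASELINE_DAYS)),
            mode=payload.get("mode", "full"),
            zt0=float(payload.get("zt0", 0.0)),
        )


def _zt_of(t: int, zt0_minute: int) -> float:
    return ((t - zt0_minute) / 60.0) % 24.0


def make_full_ssd(
    first_onset_zt: float = 4.5,
    n_episodes: int = 24,
    zt0_minute: int = DEFAULT_ZT0_MINUTE,
    baseline_days: tuple[int, ...] = DEFAULT_BASELINE_DAYS,
) -> SSDSchedule:
    """Build the full ultradian protocol.

    Episode k begins its rebound at ZT ``(first_onset_zt + 7k) mod 24``;
    with 24 episodes the onsets cover one value in every one-hour residue
    class.  The default first onset of ZT4.5 follows the protocol's worked
    example and is configurable.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    if not 0 <= first_onset_zt < 24:
        raise ValueError("first_onset_zt must lie in [0, 24)")
    first_sd_start = zt0_minute + int(round(((first_onset_zt - SD_MINUTES / 60.0) % 24.0) * 60))
    episodes = []
    for k in range(n_episodes):
        sd_start = first_sd_start + k * EPISODE_SPAN
        sd_end = sd_start + SD_MINUTES
        episodes.append(
            Episode(
                index=k,
                sd_start_t=sd_start,
                sd_end_t=sd_end,
                rebound_end_t=sd_end + REBOUND_MINUTES,
                onset_zt=_zt_of(sd_end, zt0_minute),
            )
        )
    zt0 = (-zt0_minute / 60.0) % 24.0
    return SSDSchedule(episodes=episodes, baseline_days=list(baseline_days), mode="full", zt0=zt0)


def make_abridged_ssd(
    zt0_minute: int = DEFAULT_ZT0_MINUTE,
    baseline_days: tuple[int, ...] = DEFAULT_BASELINE_DAYS,
) -> SSDSchedule:
    """Build the five-episode abridged protocol (days 3-5 of the recording)."""
    episodes = []
    for k, (day, sd_zt) in enumerate(ABRIDGED_SD_STARTS):
        sd_start = zt0_minute + day * MINUTES_PER_DAY + int(round(sd_zt * 60))
        sd_end = sd_start + SD_MINUTES
        episodes.append(
            Episode(
                index=k,
                sd_start_t=sd_start,
                sd_end_t=sd_end,
                rebound_end_t=sd_end + REBOUND_MINUTES,
                onset_zt=_zt_of(sd_end, zt0_minute),
            )
        )
    episodes.sort(key=lambda e: e.sd_start_t)
    zt0 = (-zt0_minute / 60.0) % 24.0
    return SSDSchedule(
        episodes=episodes, baseline_days=list(baseline_days), mode="abridged", zt0=zt0
    )


@dataclass
class ScheduleReport:
    overlaps: list = field(default_factory=list)
    duration_violations: list = field(default_factory=list)
    out_of_range: list = field(default_factory=list)
    residue_coverage_ok: bool = True

    @property
    def ok(self) -> bool:
        return (
            not self.overlaps
            and not self.duration_violations
            and not self.out_of_range
            and self.residue_coverage_ok
        )


def validate_schedule(
    schedule: SSDSchedule, table: ActivityTable | None = None
) -> ScheduleReport:
    """Check overlap, durations, recording coverage, and (full mode) that
    rebound onsets cover all 24 one-hour residue classes."""
    report = ScheduleReport()
    eps = sorted(schedule.episodes, key=lambda e: e.sd_start_t)
    for a, b in zip(eps[:-1], eps[1:]):
        if b.sd_start_t < a.rebound_end_t:
            report.overlaps.append((a.index, b.index))
    for e in eps:
        if e.sd_end_t - e.sd_start_t != SD_MINUTES:
            report.duration_violations.append((e.index, "sd"))
        if e.rebound_end_t - e.sd_end_t != REBOUND_MINUTES:
            report.duration_violations.append((e.index, "rebound"))
    if table is not None:
        for e in eps:
            if e.sd_start_t < 0 or e.rebound_end_t > table.n_minutes:
                report.out_of_range.append(e.index)
        for d in schedule.baseline_days:
            if (d + 1) * MINUTES_PER_DAY > table.n_minutes:
                report.out_of_range.append(f"baseline_day_{d}")
    if schedule.mode == "full" and schedule.n_episodes >= 24:
        residues = {int(e.onset_zt % 24.0) for e in eps}
        report.residue_coverage_ok = residues == set(range(24))
    elif schedule.mode == "full":
        report.residue_coverage_ok = False
    return report


def stimulus_times(
    episode: Episode,
    seed: int,
    mean_interval_s: float = 20.0,
    jitter_s: float = 0.0,
    pulse_s: float = 2.0,
) -> np.ndarray:
    """Second-resolution stimulus onsets for one SD episode.

    A 2 s vibration pulse recurs roughly every 20 s; inter-onset intervals
    are drawn uniformly from ``mean_interval_s ± jitter_s``.  Returned
    onsets are seconds since the recording start, all within the SD
    window.  Used by the simulator; reproducible under ``seed``.
    """
    del pulse_s  # recorded in the protocol but not needed for onsets
    rng = np.random.default_rng(seed)
    start_s = episode.sd_start_t * 60
    end_s = episode.sd_end_t * 60
    onsets = []
    cursor = float(start_s)
    while cursor < end_s:
        onsets.append(cursor)
        step = mean_interval_s
        if jitter_s > 0:
            step += rng.uniform(-jitter_s, jitter_s)
        cursor += max(step, 1.0)
    return np.asarray(onsets)
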