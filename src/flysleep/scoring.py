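"""Sleep scoring from per-minute activity counts.

Fly sleep is defined behaviorally as any period of at least five
consecutive minutes with zero beam crossings.  All minutes of a
qualifying inactive run are scored as sleep, including the first four;
shorter zero-runs are quiescent wake.  Runs touching the recording edges
count if they reach the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dam import ActivityTable, DamIntegrityError


@dataclass
class SleepSeries:
    """Per-fly, per-minute binary sleep state on the activity grid."""

    asleep: np.ndarray  # (n_flies, n_minutes) bool
    fly_ids: list[str]
    zt0: float = 0.0
    t: np.ndarray | None = None
    min_bout_minutes: int = 5

    def __post_init__(self) -> None:
        self.asleep = np.asarray(self.asleep, dtype=bool)
        if self.t is None:
            self.t = np.arange(self.asleep.shape[1], dtype=np.int64)

    @property
    def n_flies(self) -> int:
        return self.asleep.shape[0]

    @property
    def n_minutes(self) -> int:
        return self.asleep.shape[1]

    @property
    def zt(self) -> np.ndarray:
        return (self.zt0 + self.t / 60.0) % 24.0

    def total_sleep(self) -> np.ndarray:
        """Total scored sleep minutes per fly."""
        return self.asleep.sum(axis=1)


@dataclass(frozen=True)
class SleepBout:
    """A maximal scored-sleep run: ``duration >= min_bout_minutes``."""

    fly_id: str
    start_t: int
    duration: int


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of maximal True runs in a 1-D mask."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts, ends - starts


def _score_inactive_runs(inactive: np.ndarray, min_bout: int) -> np.ndarray:
    """Mark every maximal inactive run of length >= min_bout, row-wise.

    Rows are separated by a sentinel column so runs never bridge flies;
    the whole computation is a single flattened run-length pass.
    """
    n, T = inactive.shape
    padded = np.zeros((n, T + 1), dtype=bool)
    padded[:, :T] = inactive
    flat = padded.ravel()
    d = np.diff(np.concatenate(([False], flat, [False])).astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    keep = (ends - starts) >= min_bout
    mark = np.zeros(flat.size + 1, dtype=np.int32)
    np.add.at(mark, starts[keep], 1)
    np.add.at(mark, ends[keep], -1)
    return (np.cumsum(mark[:-1]) > 0).reshape(n, T + 1)[:, :T]


def score_sleep(table: ActivityTable, min_bout_minutes: int = 5) -> SleepSeries:
    """Score sleep with the >=``min_bout_minutes`` zero-activity rule.

    Deterministic; raises :class:`DamIntegrityError` on a gapped grid.
    """
    if min_bout_minutes < 1:
        raise ValueError("min_bout_minutes must be >= 1")
    if not table.is_gapless():
        raise DamIntegrityError("activity grid has gaps; cannot score sleep")
    asleep = _score_inactive_runs(table.counts == 0, min_bout_minutes)
    return SleepSeries(
        asleep=asleep,
        fly_ids=list(table.fly_ids),
        zt0=table.zt0,
        t=table.t.copy(),
        min_bout_minutes=min_bout_minutes,
    )


def sleep_bouts(series: SleepSeries, fly_id: str | None = None) -> list[SleepBout]:
    """Maximal, disjoint, sorted sleep bouts (optionally for one fly)."""
    out: list[SleepBout] = []
    for i, fid in enumerate(series.fly_ids):
        if fly_id is not None and fid != fly_id:
            continue
        starts, lengths = _runs(series.asleep[i])
        out.extend(
            SleepBout(fid, int(series.t[s]), int(ln)) for s, ln in zip(starts, lengths)
        )
    return out


def _check_window(series: SleepSeries, start_t: int, end_t: int) -> None:
    if start_t > end_t:
        raise ValueError(f"window start {start_t} after end {end_t}")
    lo, hi = int(series.t[0]), int(series.t[-1]) + 1
    if start_t < lo or end_t > hi:
        raise ValueError(f"window [{start_t}, {end_t}) outside extent [{lo}, {hi})")


def sleep_in_window(series: SleepSeries, start_t: int, end_t: int) -> np.ndarray:
    """Scored sleep minutes per fly in the half-open window [start_t, end_t).

    Bouts straddling a boundary contribute only their in-window minutes.
    """
    _check_window(series, start_t, end_t)
    lo = start_t - int(series.t[0])
    hi = end_t - int(series.t[0])
    return series.asleep[:, lo:hi].sum(axis=1).astype(np.int64)


def sleep_latency(
    series: SleepSeries, start_t: int, end_t: int
) -> tuple[np.ndarray, np.ndarray]:
    """Minutes from window start to the first sleep within the window.

    A bout already in progress at the window start counts as onset at the
    window start (latency 0).  Flies with no sleep in the window get
    latency equal to the window length with ``censored=True``; censored
    latencies are flagged, never dropped.
    """
    _check_window(series, start_t, end_t)
    lo = start_t - int(series.t[0])
    hi = end_t - int(series.t[0])
    window = series.asleep[:, lo:hi]
    length = hi - lo
    latency = np.full(series.n_flies, length, dtype=np.int64)
    censored = np.ones(series.n_flies, dtype=bool)
    any_sleep = window.any(axis=1)
    first = np.argmax(window, axis=1)
    latency[any_sleep] = first[any_sleep]
    censored[any_sleep] = False
    return latency, censored


def to_frame(table: ActivityTable, series: SleepSeries) -> pd.DataFrame:
    """Tabular export: fly_id, t, zt, count, asleep."""
    df = table.to_frame()
    df["asleep"] = series.asleep.ravel()
    return df
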