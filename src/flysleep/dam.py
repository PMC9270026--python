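"""Reading and writing Trikinetics-style DAM monitor files.

A Drosophila Activity Monitor (DAM) file is a tab-delimited text file with
one record per minute.  Each record carries 10 metadata columns — reading
index, date (``d MMM yy``), time (``HH:MM:SS``), a status code, five device
fields, and a light flag — followed by 32 beam-crossing counts, one per
channel (fly).  This module parses such files into :class:`ActivityTable`
objects, writes them back losslessly, and validates the per-minute grid.

Zeitgeber time (ZT) is assigned from a :class:`LightSchedule`: ZT0 is
lights-on, ZT12 is lights-off under 12:12 LD.  Under constant darkness the
same mapping is kept and read as circadian time (CT) assuming a 24.0 h
free-running period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DAM_N_CHANNELS = 32
_N_META_COLS = 10
MINUTES_PER_DAY = 1440


class DamParseError(ValueError):
    """A row could not be parsed (wrong width, bad field)."""


class DamIntegrityError(ValueError):
    """Timestamps are non-monotone or the 1-min grid has gaps."""


class DamCapacityError(ValueError):
    """More flies than a single monitor file can hold."""


@dataclass(frozen=True)
class LightSchedule:
    """Light regime used to map clock time onto zeitgeber time.

    Parameters
    ----------
    lights_on : float
        Clock hour of lights-on (ZT0), e.g. 8.0 for 08:00.
    mode : str
        ``"LD"`` for a 12:12 light:dark cycle, ``"DD"`` for constant
        darkness (ZT values are then read as CT with a 24 h period).
    """

    lights_on: float = 8.0
    mode: str = "LD"

    def __post_init__(self) -> None:
        if self.mode not in ("LD", "DD"):
            raise ValueError(f"mode must be 'LD' or 'DD', got {self.mode!r}")
        if not 0 <= self.lights_on < 24:
            raise ValueError("lights_on must lie in [0, 24)")


@dataclass
class ActivityTable:
    """Per-fly, per-minute beam-crossing counts on a gapless 1-min grid.

    ``counts`` is an ``(n_flies, n_minutes)`` integer array.  ``t`` holds
    the minute indices (0-based, shared by all flies); for a compliant
    table it is simply ``arange(n_minutes)`` but it may carry gaps when a
    table is assembled by hand, in which case :func:`validate_dam` reports
    them and downstream scoring refuses to run.  ``zt0`` is the zeitgeber
    time of minute 0.
    """

    counts: np.ndarray
    fly_ids: list[str]
    zt0: float = 0.0
    start: datetime | None = None
    mode: str = "LD"
    t: np.ndarray | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (n_flies, n_minutes)")
        if len(self.fly_ids) != self.counts.shape[0]:
            raise ValueError("fly_ids length must match counts rows")
        if self.t is None:
            self.t = np.arange(self.counts.shape[1], dtype=np.int64)
        else:
            self.t = np.asarray(self.t, dtype=np.int64)
        if self.t.shape[0] != self.counts.shape[1]:
            raise ValueError("t length must match counts columns")
        self.zt0 = float(self.zt0) % 24.0

    @property
    def n_flies(self) -> int:
        return self.counts.shape[0]

    @property
    def n_minutes(self) -> int:
        return self.counts.shape[1]

    @property
    def zt(self) -> np.ndarray:
        """Zeitgeber time (hours in [0, 24)) of every minute."""
        return (self.zt0 + self.t / 60.0) % 24.0

    def day(self) -> np.ndarray:
        """Experiment day index of every minute (day 0 starts at t=0)."""
        return self.t // MINUTES_PER_DAY

    def is_gapless(self) -> bool:
        return bool(np.all(np.diff(self.t) == 1))

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per fly per minute."""
        n, m = self.counts.shape
        return pd.DataFrame(
            {
                "fly_id": np.repeat(self.fly_ids, m),
                "t": np.tile(self.t, n),
                "zt": np.tile(self.zt, n),
                "count": self.counts.ravel(),
            }
        )

    def equals(self, other: "ActivityTable") -> bool:
        return (
            self.fly_ids == other.fly_ids
            and self.counts.shape == other.counts.shape
            and bool(np.array_equal(self.counts, other.counts))
            and bool(np.array_equal(self.t, other.t))
            and abs(((self.zt0 - other.zt0) + 12) % 24 - 12) < 1e-9
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dam`; empty lists mean a compliant table."""

    gaps: dict = field(default_factory=dict)          # fly_id -> n gaps
    negative_counts: list = field(default_factory=list)  # (fly_id, t)
    zt_violations: int = 0

    @property
    def ok(self) -> bool:
        return not self.gaps and not self.negative_counts and self.zt_violations == 0

    def summary(self) -> str:
        if self.ok:
            return "OK: no violations"
        return (
            f"{sum(self.gaps.values())} gap(s) in {len(self.gaps)} fly(ies); "
            f"{len(self.negative_counts)} negative count(s); "
            f"{self.zt_violations} zt-range violation(s)"
        )


def _parse_row(line: str, lineno: int) -> tuple[datetime, int, int, list[int]]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != _N_META_COLS + DAM_N_CHANNELS:
        raise DamParseError(
            f"line {lineno}: expected {_N_META_COLS + DAM_N_CHANNELS} "
            f"tab-separated columns, got {len(parts)}"
        )
    try:
        when = datetime.strptime(f"{parts[1]} {parts[2]}", "%d %b %y %H:%M:%S")
        status = int(parts[3])
        light = int(parts[9])
        counts = [int(c) for c in parts[_N_META_COLS:]]
    except ValueError as exc:
        raise DamParseError(f"line {lineno}: {exc}") from exc
    return when, status, light, counts


def read_dam(
    path: str | Path,
    light_schedule: LightSchedule = LightSchedule(),
    valid_status: int = 1,
) -> ActivityTable:
    """Read a DAM monitor file into an :class:`ActivityTable`.

    Records whose status differs from ``valid_status`` are excluded and
    counted (``table.n_excluded``).  Exclusions are only tolerated at the
    edges of the recording: an interior exclusion (or a missing minute)
    would break the gapless 1-min grid and raises
    :class:`DamIntegrityError` — gaps are an error, never silently filled.
    """
    path = Path(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rows.append(_parse_row(line, lineno))
    if not rows:
        raise DamParseError(f"{path}: no records")

    status = np.array([r[1] for r in rows])
    valid = status == valid_status
    n_excluded = int((~valid).sum())
    if n_excluded:
        log.info("%s: excluded %d record(s) with status != %d", path, n_excluded, valid_status)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        raise DamIntegrityError(f"{path}: all records have invalid status")
    first, last = idx[0], idx[-1]
    if not np.all(valid[first : last + 1]):
        raise DamIntegrityError(
            f"{path}: invalid-status record(s) interior to the recording leave "
            "gaps in the 1-min grid"
        )
    rows = rows[first : last + 1]

    times = [r[0] for r in rows]
    deltas = {(b - a).total_seconds() for a, b in zip(times[:-1], times[1:])}
    if deltas and deltas != {60.0}:
        raise DamIntegrityError(f"{path}: timestamps are not consecutive 1-min readings")

    counts = np.array([r[3] for r in rows], dtype=np.int64).T  # (32, T)
    if np.any(counts < 0):
        raise DamParseError(f"{path}: negative counts")
    start = times[0]
    clock0 = start.hour + start.minute / 60.0 + start.second / 3600.0
    zt0 = (clock0 - light_schedule.lights_on) % 24.0
    stem = path.stem
    fly_ids = [f"{stem}#{ch + 1:02d}" for ch in range(DAM_N_CHANNELS)]
    return ActivityTable(
        counts=counts,
        fly_ids=fly_ids,
        zt0=zt0,
        start=start,
        mode=light_schedule.mode,
        n_excluded=n_excluded,
    )


def write_dam(
    table: ActivityTable,
    path: str | Path,
    light_schedule: LightSchedule = LightSchedule(),
    valid_status: int = 1,
) -> Path:
    """Write an :class:`ActivityTable` as a standard 32-channel DAM file.

    The output is byte-stable for identical input and round-trips through
    :func:`read_dam` losslessly (counts, times, total count mass).  Tables
    with fewer than 32 flies fill the remaining channels with zeros; more
    than 32 flies is a capacity error.
    """
    if table.n_flies == 0:
        raise ValueError("cannot write an empty cohort (no flies)")
    if table.n_flies > DAM_N_CHANNELS:
        raise DamCapacityError(
            f"{table.n_flies} flies exceed the {DAM_N_CHANNELS}-channel monitor capacity"
        )
    if not table.is_gapless():
        raise DamIntegrityError("table grid has gaps; refusing to write")
    path = Path(path)

    start = table.start
    if start is None:
        # Place minute 0 at the clock time implied by zt0 and lights-on.
        clock0 = (light_schedule.lights_on + table.zt0) % 24.0
        start = datetime(2021, 1, 1) + timedelta(hours=clock0)

    counts = np.zeros((DAM_N_CHANNELS, table.n_minutes), dtype=np.int64)
    counts[: table.n_flies] = table.counts
    zt = table.zt

    lines = []
    for j in range(table.n_minutes):
        when = start + timedelta(minutes=int(table.t[j]))
        light = 1 if (table.mode == "LD" and zt[j] < 12.0) else 0
        meta = [
            str(j + 1),
            f"{when.day} {when.strftime('%b %y')}",
            when.strftime("%H:%M:%S"),
            str(valid_status),
            "1", "0", "0", "0", "0",
            str(light),
        ]
        lines.append("\t".join(meta + [str(int(c)) for c in counts[:, j]]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def validate_dam(table: ActivityTable) -> ValidationReport:
    """Report grid gaps, negative counts, and out-of-range zt values."""
    report = ValidationReport()
    n_gaps = int(np.sum(np.diff(table.t) != 1))
    if n_gaps:
        report.gaps = {fid: n_gaps for fid in table.fly_ids}
    neg = np.argwhere(table.counts < 0)
    report.negative_counts = [(table.fly_ids[i], int(table.t[j])) for i, j in neg]
    zt = table.zt
    report.zt_violations = int(np.sum((zt < 0) | (zt >= 24)))
    return report
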