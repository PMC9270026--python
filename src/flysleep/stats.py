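"""Rebound heatmaps, matched morning/evening selection, and hypothesis tests.

The rebound heatmap is a matrix of cohort-mean sleep per 30-min post-SD
bin (columns, 9 × 30 min over the 4.5 h rebound) by rebound-onset ZT
(rows).  Onset rows not visited by the protocol are filled by
column-wise linear interpolation along the ZT axis, treated circularly
by default because zeitgeber time is periodic; observed rows are never
touched by interpolation.

Morning/evening comparisons use time points matched on two potential
confounds — mean sleep lost and mean baseline sleep in the rebound
window — selected by exhaustive search over morning ([0, 6) ZT) and
evening ([6, 12) ZT) candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .profiles import DailyProfile, baseline_sleep_profile
from .schedule import REBOUND_MINUTES, SSDSchedule
from .scoring import SleepSeries


@dataclass
class ReboundHeatmap:
    rows_zt: np.ndarray        # sorted onset ZTs in [0, 24)
    bin_minutes: int
    values: np.ndarray         # (n_rows, n_bins) mean sleep minutes per bin
    observed_mask: np.ndarray  # True where the row was measured

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"min_{b * self.bin_minutes}" for b in range(self.n_bins)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "onset_zt", self.rows_zt)
        df.insert(1, "observed", self.observed_mask)
        return df


def _interp_rows(
    grid: np.ndarray, observed_zt: np.ndarray, observed: np.ndarray, wrap: str
) -> np.ndarray:
    """Column-wise linear interpolation of missing onset rows."""
    order = np.argsort(observed_zt)
    xs = observed_zt[order]
    ys = observed[order]
    out = np.empty((len(grid), observed.shape[1]))
    for c in range(observed.shape[1]):
        if wrap == "circular":
            x_ext = np.concatenate(([xs[-1] - 24.0], xs, [xs[0] + 24.0]))
            y_ext = np.concatenate(([ys[-1, c]], ys[:, c], [ys[0, c]]))
            out[:, c] = np.interp(grid, x_ext, y_ext)
        else:  # clamp at the ZT edges
            out[:, c] = np.interp(grid, xs, ys[:, c])
    return out


def rebound_heatmap(
    series: SleepSeries,
    schedule: SSDSchedule,
    retained: list[str] | None = None,
    bin_minutes: int = 30,
    wrap: str = "circular",
    row_grid: np.ndarray | None = None,
) -> ReboundHeatmap:
    """Cohort-mean rebound sleep by onset ZT and post-SD bin.

    Rows are the union of the observed onsets with a uniform 24-row grid
    sharing their fractional offset (so a complete 24-episode protocol
    yields no interpolated rows, and the abridged protocol interpolates
    the 19 unvisited rows).
    """
    if not schedule.episodes:
        raise ValueError("schedule has no episodes")
    if REBOUND_MINUTES % bin_minutes:
        raise ValueError("bin_minutes must divide the rebound window")
    if wrap not in ("circular", "clamp"):
        raise ValueError("wrap must be 'circular' or 'clamp'")
    n_bins = REBOUND_MINUTES // bin_minutes
    fly_sel = (
        np.ones(series.n_flies, dtype=bool)
        if retained is None
        else np.isin(series.fly_ids, retained)
    )
    if not fly_sel.any():
        raise ValueError("no retained flies")

    observed_zt = []
    observed_vals = []
    for e in schedule.episodes:
        start, end = e.rebound_window
        window = series.asleep[fly_sel, start:end]
        per_bin = window.reshape(window.shape[0], n_bins, bin_minutes).sum(axis=2)
        observed_zt.append(e.onset_zt)
        observed_vals.append(per_bin.mean(axis=0))
    observed_zt = np.asarray(observed_zt)
    observed_vals = np.asarray(observed_vals)

    if row_grid is None:
        fracs = np.round(observed_zt % 1.0, 6)
        if np.all(fracs == fracs[0]):
            row_grid = fracs[0] + np.arange(24.0)
        else:
            row_grid = np.sort(observed_zt)
    grid = np.unique(np.round(np.concatenate([row_grid, observed_zt]), 6))

    values = _interp_rows(grid, observed_zt, observed_vals, wrap)
    mask = np.isin(grid, np.round(observed_zt, 6))
    # observed rows carry the measured values exactly
    for z, v in zip(np.round(observed_zt, 6), observed_vals):
        values[grid == z] = v
    return ReboundHeatmap(
        rows_zt=grid, bin_minutes=bin_minutes, values=values, observed_mask=mask
    )


def baseline_heatmap(
    series: SleepSeries, baseline_days: list[int], bin_minutes: int = 30
) -> DailyProfile:
    """The heatmap's lower band: mean baseline sleep per clock bin."""
    return baseline_sleep_profile(series, baseline_days, bin_minutes)


@dataclass
class MatchedPair:
    found: bool
    morning_zt: float = float("nan")
    evening_zt: float = float("nan")
    delta_baseline: float = float("nan")
    delta_lost: float = float("nan")
    score: float = float("nan")
    reason: str = ""


def match_morning_evening(
    summaries: pd.DataFrame,
    tol_baseline: float = 45.0,
    tol_lost: float = 45.0,
    w_baseline: float = 1.0,
    w_lost: float = 1.0,
    morning_range: tuple[float, float] = (0.0, 6.0),
    evening_range: tuple[float, float] = (6.0, 12.0),
) -> MatchedPair:
    """Select the baseline- and deprivation-matched morning/evening pair.

    ``summaries`` needs columns ``onset_zt``, ``mean_baseline_rebound``,
    ``mean_lost``.  The pair minimizing the weighted sum of absolute
    deltas (each standardized by its SD across candidates) wins; ties are
    broken by smaller raw |Δ baseline|, then smaller morning ZT.  Returns
    an explicit no-match result when no pair meets both tolerances.
    """
    m = summaries[
        (summaries["onset_zt"] >= morning_range[0]) & (summaries["onset_zt"] < morning_range[1])
    ]
    e = summaries[
        (summaries["onset_zt"] >= evening_range[0]) & (summaries["onset_zt"] < evening_range[1])
    ]
    if m.empty or e.empty:
        return MatchedPair(found=False, reason="no morning or no evening candidates")
    cand = pd.concat([m, e])
    sd_b = float(cand["mean_baseline_rebound"].std(ddof=0)) or 1.0
    sd_l = float(cand["mean_lost"].std(ddof=0)) or 1.0

    best: MatchedPair | None = None
    best_key: tuple | None = None
    for _, rm in m.iterrows():
        for _, re_ in e.iterrows():
            db = abs(rm["mean_baseline_rebound"] - re_["mean_baseline_rebound"])
            dl = abs(rm["mean_lost"] - re_["mean_lost"])
            if db > tol_baseline or dl > tol_lost:
                continue
            score = w_baseline * db / sd_b + w_lost * dl / sd_l
            key = (score, db, rm["onset_zt"])
            if best_key is None or key < best_key:
                best_key = key
                best = MatchedPair(
                    found=True,
                    morning_zt=float(rm["onset_zt"]),
                    evening_zt=float(re_["onset_zt"]),
                    delta_baseline=float(db),
                    delta_lost=float(dl),
                    score=float(score),
                )
    if best is None:
        return MatchedPair(found=False, reason="no pair within tolerances")
    return best


@dataclass
class TestResult:
    test: str
    statistic: float
    df: float
    p: float
    n: int
    degenerate: bool = False
    note: str = ""


def paired_comparison(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided paired t-test (flies paired with themselves across time points)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        return TestResult("paired_t", float("nan"), float("nan"), float("nan"), n,
                          degenerate=True, note="n < 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        return TestResult("paired_t", float("nan"), n - 1, float("nan"), n,
                          degenerate=True, note="zero-variance differences")
    t, p = sps.ttest_rel(x, y)
    return TestResult("paired_t", float(t), n - 1, float(p), n)


@dataclass
class GroupComparison:
    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj (Tukey HSD)
    degenerate: bool = False


def group_comparison(samples: dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA across groups with Tukey-HSD-adjusted pairwise follow-ups."""
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(samples[g], dtype=float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    k = len(arrays)
    if np.allclose(pooled.std(ddof=0), 0.0):
        pairwise = pd.DataFrame(
            [(a, b, 0.0, 1.0) for i, a in enumerate(names) for b in names[i + 1:]],
            columns=["group1", "group2", "meandiff", "p_adj"],
        )
        return GroupComparison(0.0, k - 1, len(pooled) - k, 1.0, pairwise, degenerate=True)
    F, p = sps.f_oneway(*arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(pooled, labels)
    pairwise = pd.DataFrame(
        tk.summary().data[1:], columns=[c for c in tk.summary().data[0]]
    )[["group1", "group2", "meandiff", "p-adj"]].rename(columns={"p-adj": "p_adj"})
    return GroupComparison(float(F), k - 1, len(pooled) - k, float(p), pairwise)


@dataclass
class TrendResult:
    slope: float
    intercept: float
    p: float
    r: float
    n: int


def gain_trend(mean_gains: np.ndarray, episode_indices: np.ndarray | None = None) -> TrendResult:
    """OLS slope of per-episode cohort mean gain against episode order.

    A flat trend (p > 0.05) indicates flies fully recover within each
    cycle rather than accumulating sleep debt across the protocol.
    """
    y = np.asarray(mean_gains, dtype=float)
    if episode_indices is None:
        episode_indices = np.arange(len(y))
    x = np.asarray(episode_indices, dtype=float)
    if len(y) < 3:
        raise ValueError("trend regression needs >= 3 episodes")
    res = sps.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p=float(res.pvalue),
        r=float(res.rvalue),
        n=len(y),
    )
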