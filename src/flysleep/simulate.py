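"""Synthetic fly-activity generator.

Generates minute-resolution DAM-style beam-crossing counts for cohorts
of simulated flies, with the circadian and homeostatic structure the
pipeline is meant to measure:

* a two-state (wake/sleep) per-minute Markov renewal process whose bout
  durations are geometric, with a hard 5-min minimum on sleep bouts so
  simulated inactive time is exactly what the 5-min scoring rule
  recovers (the cornerstone identity for recovery tests);
* a circadian sleep-propensity curve ``f(zt)`` with wake peaks around
  lights-on and lights-off (the classic bimodal fly activity profile),
  elevated night sleep, and a midday siesta — the stationary sleep
  fraction of the chain is pinned to ``f``;
* a mild sleep-debt homeostat (mechanistic mode) that raises sleep
  propensity after enforced wakefulness;
* near-complete forced wakefulness during scheduled-deprivation windows
  (each SD minute independently forces wake with probability ``eta``);
* a *gain-injection* mode in which the rebound-window process is
  re-weighted so the expected scored sleep equals ``B(zt) + g(zt)``,
  where ``B`` is the model's expected baseline sleep for that clock
  window and ``g`` an arbitrary feasible time-of-day gain profile —
  making the pipeline's expected measured sleep gain equal ``g``.

Wake minutes always emit at least one count, so wakefulness can never be
mis-scored as sleep.  Each fly draws from an independent random
substream derived from ``(seed, fly_index)``: growing the cohort never
perturbs existing flies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dam import ActivityTable, MINUTES_PER_DAY
from .rebound import clock_window_indices
from .schedule import REBOUND_MINUTES, SSDSchedule
from .scoring import _score_inactive_runs, score_sleep


class SimConfigError(ValueError):
    """A generator configuration violates its invariants."""


DEFAULT_GAIN_ANCHORS: dict[float, float] = {
    # ZT1.5 and ZT9.5 carry the morning/evening rebound gains the study
    # design centers on; the remaining anchors shape a plausible smooth
    # profile (low at night where baseline sleep leaves little headroom).
    1.5: 133.0,
    5.5: 110.0,
    9.5: 51.0,
    13.5: 35.0,
    17.5: 20.0,
    21.5: 40.0,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Circadian gate: the sleep-propensity curve is
    ``f(zt) = f_mid + f_amp·cos(2π(zt−night_peak_zt)/24) − dips`` with
    wrapped-Gaussian wake dips after lights-on and before lights-off,
    clipped to ``[f_floor, f_ceil]``.  Mean sleep bout is
    ``5 + sleep_bout_scale·f`` minutes; mean wake bout follows from the
    stationary-fraction constraint ``μ_w = μ_s(1−f)/f``.
    """

    n_flies: int = 32
    seed: int = 0
    mode: str = "mechanistic"  # or "gain_injection"

    # circadian sleep-propensity curve
    f_mid: float = 0.62
    f_amp: float = 0.18
    night_peak_zt: float = 18.0
    dip_morning_zt: float = 1.0
    dip_morning_sigma: float = 1.8
    dip_morning_depth: float = 0.30
    dip_evening_zt: float = 11.0
    dip_evening_sigma: float = 1.8
    dip_evening_depth: float = 0.35
    f_floor: float = 0.05
    f_ceil: float = 0.95

    # bout model
    sleep_bout_scale: float = 40.0  # minutes of mean sleep bout per unit propensity
    min_sleep_bout: int = 5         # hard floor; keeps scored == simulated sleep

    # homeostat (mechanistic mode only): sleep debt in wake-minutes
    debt_weight: float = 0.003      # propensity boost per accumulated debt minute
    debt_decay: float = 1.5         # debt minutes repaid per sleep minute

    # activity emission and stimulation
    activity_rate: float = 1.5      # Poisson rate on top of the guaranteed 1 count
    eta: float = 0.99               # per-minute forced-wake probability during SD

    # gain-injection profile: ZT -> injected expected sleep gain (minutes)
    gain_anchors: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_GAIN_ANCHORS)
    )

    def __post_init__(self) -> None:
        if self.mode not in ("mechanistic", "gain_injection"):
            raise SimConfigError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise SimConfigError("eta must lie in [0, 1]")
        if self.activity_rate <= 0:
            raise SimConfigError("activity_rate must be positive")
        if self.min_sleep_bout < 5:
            raise SimConfigError("min_sleep_bout below 5 breaks the scoring identity")
        if not 0 < self.f_floor < self.f_ceil < 1:
            raise SimConfigError("need 0 < f_floor < f_ceil < 1")

    def key(self) -> tuple:
        """Hashable identity used to cache baseline-sleep estimates."""
        return (
            self.seed, self.mode, self.f_mid, self.f_amp, self.night_peak_zt,
            self.dip_morning_zt, self.dip_morning_sigma, self.dip_morning_depth,
            self.dip_evening_zt, self.dip_evening_sigma, self.dip_evening_depth,
            self.f_floor, self.f_ceil, self.sleep_bout_scale, self.min_sleep_bout,
            self.debt_weight, self.debt_decay, self.activity_rate,
        )


def _wrapped_gauss(zt: np.ndarray, center: float, sigma: float) -> np.ndarray:
    d = np.abs((zt - center + 12.0) % 24.0 - 12.0)
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2))


def circadian_sleep_fraction(config: SimConfig, zt: np.ndarray) -> np.ndarray:
    """Target stationary sleep fraction at each zeitgeber time."""
    zt = np.asarray(zt, dtype=float)
    f = (
        config.f_mid
        + config.f_amp * np.cos(2 * np.pi * (zt - config.night_peak_zt) / 24.0)
        - config.dip_morning_depth
        * _wrapped_gauss(zt, config.dip_morning_zt, config.dip_morning_sigma)
        - config.dip_evening_depth
        * _wrapped_gauss(zt, config.dip_evening_zt, config.dip_evening_sigma)
    )
    return np.clip(f, config.f_floor, config.f_ceil)


def gain_profile(config: SimConfig, zt: float | np.ndarray) -> np.ndarray:
    """Injected gain g(zt), circular linear interpolation of the anchors."""
    anchors = sorted(config.gain_anchors.items())
    if not anchors:
        raise SimConfigError("gain_anchors is empty")
    xs = np.array([a for a, _ in anchors])
    ys = np.array([g for _, g in anchors])
    x_ext = np.concatenate(([xs[-1] - 24.0], xs, [xs[0] + 24.0]))
    y_ext = np.concatenate(([ys[-1]], ys, [ys[0]]))
    return np.interp(np.asarray(zt, dtype=float) % 24.0, x_ext, y_ext)


# ---------------------------------------------------------------------------
# core two-state chain
# ---------------------------------------------------------------------------

def _transition_probs(f: np.ndarray, mu_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute wake->sleep and (unlocked) sleep->wake probabilities.

    Sleep bouts are 5 + Geometric(mean mu_s − 5) minutes; wake bouts are
    Geometric(mean mu_s(1−f)/f), so the stationary sleep fraction is f.
    """
    mu_s = np.maximum(mu_s, 5.0)
    mu_w = np.maximum(mu_s * (1.0 - f) / np.maximum(f, 1e-9), 1.02)
    p_ws = np.clip(1.0 / mu_w, 0.0, 0.98)
    p_sw = np.clip(1.0 / (mu_s - 4.0), 1e-9, 1.0)
    return p_ws, p_sw


def _simulate_chain(
    f_t: np.ndarray,
    mu_s_t: np.ndarray,
    sd_mask: np.ndarray,
    eta: float,
    u_trans: np.ndarray,
    u_force: np.ndarray,
    extra_counts: np.ndarray,
    debt_weight: float,
    debt_decay: float,
    f_ceil: float,
) -> np.ndarray:
    """Run the per-minute chain for a block of flies sharing a timeline.

    ``f_t``/``mu_s_t`` are (T,) schedules; ``u_trans``/``u_force``/
    ``extra_counts`` are (n, T) pre-drawn randoms (one row per fly, so
    per-fly streams stay independent).  Returns (n, T) counts.
    """
    n, T = u_trans.shape
    counts = np.zeros((n, T), dtype=np.int64)
    asleep = np.zeros(n, dtype=bool)
    lock = np.zeros(n, dtype=np.int64)
    debt = np.zeros(n, dtype=float)
    use_debt = debt_weight > 0
    for t in range(T):
        f = f_t[t]
        if use_debt:
            f_eff = f + (f_ceil - f) * (1.0 - np.exp(-debt_weight * debt))
        else:
            f_eff = np.full(n, f)
        p_ws, p_sw = _transition_probs(f_eff, np.full(n, mu_s_t[t]))
        u = u_trans[:, t]
        falling_asleep = (~asleep) & (u < p_ws)
        waking = asleep & (lock == 0) & (u < p_sw)
        lock[asleep & (lock > 0)] -= 1
        asleep = (asleep & ~waking) | falling_asleep
        lock[falling_asleep] = 4
        if sd_mask[t] and eta > 0:
            forced = u_force[:, t] < eta
            asleep &= ~forced
            lock[forced] = 0
        counts[~asleep, t] = 1 + extra_counts[~asleep, t]
        if use_debt:
            debt = np.where(asleep, np.maximum(debt - debt_decay, 0.0), debt + 1.0)
    return counts


def _fly_randoms(
    config: SimConfig, fly_indices: range, T: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-draw per-fly random streams derived from (seed, fly_index)."""
    u_trans = np.empty((len(fly_indices), T))
    u_force = np.empty((len(fly_indices), T))
    extra = np.empty((len(fly_indices), T), dtype=np.int64)
    for row, i in enumerate(fly_indices):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        u_trans[row] = rng.random(T)
        u_force[row] = rng.random(T)
        extra[row] = rng.poisson(config.activity_rate, T)
    return u_trans, u_force, extra


# ---------------------------------------------------------------------------
# baseline expectation and gain calibration
# ---------------------------------------------------------------------------

_BASELINE_CACHE: dict[tuple, np.ndarray] = {}
_BASELINE_N_FLIES = 150
_BASELINE_N_DAYS = 3
_BASELINE_SKIP_DAYS = 1  # burn-in: the chain starts awake at minute 0


def _baseline_sleep_matrix(config: SimConfig) -> np.ndarray:
    """Scored sleep of an undisturbed reference cohort (cached per config).

    A fixed internal substream (independent of the cohort flies) drives
    this estimator, so it is deterministic given ``config.seed``.
    """
    key = config.key()
    if key not in _BASELINE_CACHE:
        T = _BASELINE_N_DAYS * MINUTES_PER_DAY
        zt = (np.arange(T) / 60.0) % 24.0
        f_t = circadian_sleep_fraction(config, zt)
        mu_s_t = config.min_sleep_bout + config.sleep_bout_scale * f_t
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0B45E11E]))
        n = _BASELINE_N_FLIES
        counts = _simulate_chain(
            f_t,
            mu_s_t,
            np.zeros(T, dtype=bool),
            0.0,
            rng.random((n, T)),
            rng.random((n, T)),
            rng.poisson(config.activity_rate, (n, T)),
            0.0,  # homeostat off: undisturbed flies carry no enforced debt
            config.debt_decay,
            config.f_ceil,
        )
        table = ActivityTable(counts=counts, fly_ids=[f"ref{i}" for i in range(n)], zt0=0.0)
        _BASELINE_CACHE[key] = score_sleep(table, config.min_sleep_bout).asleep
    return _BASELINE_CACHE[key]


def expected_baseline_sleep(
    config: SimConfig, start_zt: float, length_min: int = REBOUND_MINUTES
) -> float:
    """Expected scored sleep (minutes) in an undisturbed clock window.

    Estimated as the long-run average over a fixed-seed reference cohort;
    used as ``B(zt)`` when calibrating gain injection.
    """
    asleep = _baseline_sleep_matrix(config)
    days = range(_BASELINE_SKIP_DAYS, _BASELINE_N_DAYS)
    vals = []
    for d in days:
        idx = clock_window_indices(d, start_zt, length_min, zt0=0.0)
        idx = idx[idx < asleep.shape[1]]
        if len(idx) == length_min:
            vals.append(asleep[:, idx].sum(axis=1))
    return float(np.mean(vals))


def window_sleep_samples(
    f: np.ndarray,
    config: SimConfig,
    T: int,
    reps: int,
    rng: np.random.Generator,
    start_awake: bool = True,
) -> np.ndarray:
    """Scored in-window sleep for constant-parameter windows, (m, reps).

    Simulates ``reps`` independent windows per candidate sleep fraction
    (starting awake, as flies do immediately after stimulation), scores
    them with the 5-min rule on a trace extended 10 min past the window
    so bouts straddling the window end are credited.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    m = len(f)
    Text = T + 10
    fr = np.repeat(f, reps)
    mu_s = config.min_sleep_bout + config.sleep_bout_scale * fr
    p_ws, p_sw = _transition_probs(fr, mu_s)
    n = m * reps
    if start_awake:
        asleep = np.zeros(n, dtype=bool)
    else:
        asleep = rng.random(n) < fr
    lock = np.zeros(n, dtype=np.int64)
    inactive = np.zeros((n, Text), dtype=bool)
    u_all = rng.random((Text, n))
    for t in range(Text):
        u = u_all[t]
        falling = (~asleep) & (u < p_ws)
        waking = asleep & (lock == 0) & (u < p_sw)
        lock[asleep & (lock > 0)] -= 1
        asleep = (asleep & ~waking) | falling
        lock[falling] = 4
        inactive[:, t] = asleep
    # 5-min scoring on the extended trace, then count in-window minutes
    scored = _score_inactive_runs(inactive, config.min_sleep_bout)
    return scored[:, :T].sum(axis=1).reshape(m, reps)


def _window_sleep_mean(
    f: np.ndarray, config: SimConfig, T: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    return window_sleep_samples(f, config, T, reps, rng).mean(axis=1)


def calibrate_injection(
    config: SimConfig, targets: np.ndarray, T: int = REBOUND_MINUTES,
    reps: int = 512, iters: int = 16,
) -> np.ndarray:
    """Solve for per-episode sleep fractions whose expected scored
    window sleep (starting awake) matches ``targets`` (minutes).

    Monotone bisection against a fixed-internal-seed window simulator
    with common random numbers across iterations.
    """
    targets = np.asarray(targets, dtype=float)
    if np.any(targets < 0) or np.any(targets > 0.98 * T):
        raise SimConfigError("injected targets outside the attainable window range")
    lo = np.full(len(targets), config.f_floor)
    hi = np.full(len(targets), 0.985)
    seed = np.random.SeedSequence([config.seed, 0xCA11B])
    for it in range(iters):
        mid = 0.5 * (lo + hi)
        rng = np.random.default_rng(seed)  # common random numbers each iteration
        got = _window_sleep_mean(mid, config, T, reps, rng)
        too_low = got < targets
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def inject_rebound_gain(config: SimConfig, episode, B: float | None = None) -> tuple[float, float]:
    """Rebound-window sleep fraction realizing the injected gain.

    Returns ``(f_star, target_minutes)`` where ``target = B(onset_zt) +
    g(onset_zt)``.  Raises :class:`SimConfigError` when the gain is
    infeasible for the window (g outside [−B, 270 − B]).
    """
    if config.mode != "gain_injection":
        raise SimConfigError("inject_rebound_gain requires gain_injection mode")
    g = float(gain_profile(config, episode.onset_zt))
    if B is None:
        B = expected_baseline_sleep(config, episode.onset_zt, REBOUND_MINUTES)
    target = B + g
    if not 0.0 <= target <= 0.98 * REBOUND_MINUTES:
        raise SimConfigError(
            f"injected gain {g:.0f} min at ZT{episode.onset_zt} is infeasible "
            f"(baseline {B:.0f} min in a {REBOUND_MINUTES}-min window)"
        )
    f_star = float(calibrate_injection(config, np.array([target]))[0])
    return f_star, target


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def required_days(schedule: SSDSchedule | None) -> int:
    if schedule is None:
        return 3
    return int(np.ceil(schedule.end_t / MINUTES_PER_DAY))


def simulate_cohort(
    config: SimConfig,
    schedule: SSDSchedule | None = None,
    n_days: int | None = None,
) -> ActivityTable:
    """Simulate a cohort through (optionally) an SSD protocol.

    Output is an :class:`ActivityTable` on a gapless grid starting at
    lights-on (zt0 = 0), reproducible under ``config.seed``.
    """
    if n_days is None:
        n_days = required_days(schedule)
    T = n_days * MINUTES_PER_DAY
    if schedule is not None and schedule.end_t > T:
        raise ValueError(
            f"schedule runs to minute {schedule.end_t} but the recording is {T} min"
        )
    zt = (np.arange(T) / 60.0) % 24.0
    f_t = circadian_sleep_fraction(config, zt)
    mu_s_t = config.min_sleep_bout + config.sleep_bout_scale * f_t

    sd_mask = np.zeros(T, dtype=bool)
    if schedule is not None:
        for e in schedule.episodes:
            sd_mask[e.sd_start_t : e.sd_end_t] = True

    debt_weight = config.debt_weight
    if config.mode == "gain_injection":
        debt_weight = 0.0  # injection pins the rebound process directly
        if schedule is None:
            raise SimConfigError("gain_injection mode needs a schedule")
        onsets = np.array([e.onset_zt for e in schedule.episodes])
        Bs = np.array(
            [expected_baseline_sleep(config, oz, REBOUND_MINUTES) for oz in onsets]
        )
        gains = gain_profile(config, onsets)
        targets = Bs + gains
        if np.any(targets < 0) or np.any(targets > 0.98 * REBOUND_MINUTES):
            bad = np.flatnonzero((targets < 0) | (targets > 0.98 * REBOUND_MINUTES))
            raise SimConfigError(
                f"infeasible injected gains at onsets {onsets[bad].tolist()}"
            )
        f_stars = calibrate_injection(config, targets)
        for e, fs in zip(schedule.episodes, f_stars):
            f_t[e.sd_end_t : e.rebound_end_t] = fs
            mu_s_t[e.sd_end_t : e.rebound_end_t] = (
                config.min_sleep_bout + config.sleep_bout_scale * fs
            )

    u_trans, u_force, extra = _fly_randoms(config, range(config.n_flies), T)
    counts = _simulate_chain(
        f_t, mu_s_t, sd_mask, config.eta, u_trans, u_force, extra,
        debt_weight, config.debt_decay, config.f_ceil,
    )
    fly_ids = [f"sim{i:03d}" for i in range(config.n_flies)]
    return ActivityTable(counts=counts, fly_ids=fly_ids, zt0=0.0)
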