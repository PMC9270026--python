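# Methods notes

## Time conventions

Recordings live on a 0-based, gapless 1-min grid; all windows are
half-open `[start, end)`. Zeitgeber time is `zt(t) = (zt0 + t/60) mod 24`
for a single configured `zt0` (the ZT of minute 0); lights-on defines
ZT0. Under constant darkness the identical mapping is kept and read as
circadian time with an assumed 24.0 h free-running period, so morning
and evening comparisons at CT2.5/CT10.5 need no phase re-estimation.

The canonical experiment starts at lights-on of day 0: day 0 is
acclimation, days 1–2 are the two full undisturbed baseline days, and
the protocol begins on day 3 (which also matches the abridged
protocol's printed day numbering). The full protocol's first rebound
onset defaults to ZT4.5 — the worked-example value — and is
configurable, since the exact first episode of a given run is an
experimental choice.

## Sleep scoring

Sleep is any maximal run of ≥5 zero-count minutes; all minutes of a
qualifying run count, including the first four, and runs touching the
recording edges are kept. This whole-bout convention is the standard
fly-sleep reading of "5 minutes of inactivity" as a threshold. Latency
is measured from the window start (the end of SD, for post-SD latency)
to the first scored sleep minute in the window; a bout already in
progress counts as latency 0, and windows without sleep yield a
censored latency equal to the window length — flagged, never dropped,
so downstream users can decide how to treat censoring.

## Baseline windows

For an episode window at clock position `[z, z + L)`, the baseline
reference is the mean over the two baseline days of scored sleep in the
same clock span, mapped *circularly within each baseline day*. The wrap
matters for episodes straddling midnight (e.g. the abridged ZT23
stimulation): mapping by clock time without the wrap would let the
window run into protocol days and contaminate the baseline.

## Efficiency filter

A fly is retained only if it lost more than 90% of baseline sleep at
*every* episode where the baseline SD-window sleep was positive (the
plain per-fly reading of "each SD interval"); a per-episode variant
that drops individual fly × episode records is available via
`apply_efficiency_filter(..., per="episode")`. Episodes with zero
baseline sleep in the SD window cannot constrain efficiency — there was
nothing to deprive — and are logged as vacuous rather than failing the
fly.

## Heatmaps and matching

The rebound heatmap has one row per rebound-onset ZT and nine 30-min
post-SD columns. Rows not visited by the protocol are filled by
column-wise linear interpolation along the onset axis, treated
circularly (ZT24 wraps to ZT0) because zeitgeber time is periodic; a
clamped mode is available. Observed rows are written from the measured
means and never touched by interpolation.

Morning/evening matching selects, among morning ([0, 6) ZT) and evening
([6, 12) ZT) onsets, the pair minimizing
`w_b·|Δ mean baseline rebound-window sleep|/σ_b + w_l·|Δ mean sleep lost|/σ_l`
with equal default weights, each delta standardized by its SD across
candidates; pairs violating the absolute tolerances (default 45 min on
both deltas) are inadmissible, ties break on smaller raw |Δ baseline|
then smaller morning ZT. The matching criterion is deliberately
exposed as configuration because it is qualitative in origin.

Statistics: paired two-sided *t* for matched time points (flies paired
with themselves), one-way ANOVA with Tukey-HSD-adjusted pairwise
follow-ups for multi-group comparisons, and OLS regression of
per-episode cohort mean gain on episode order for the across-protocol
trend. Degenerate inputs (zero-variance differences, n < 2) return
flagged results instead of spurious p-values.

## Anticipation index

The index is the normalized contrast `(A_near − A_far)/(A_near + A_far)`
between summed activity in the 3 h immediately before a light
transition and the 3 h before that, mirrored at ZT12 for lights-off.
This form is bounded in [−1, 1], admits small negative values, and is
invariant to uniform count scaling; window lengths are configurable.
It is one of several indices in use in the field, so absolute values
should only be compared within a fixed choice of formula.

## Synthetic cohorts

The generator is a per-minute two-state (wake/sleep) Markov renewal
process. Wake bouts are geometric; sleep bouts are 5 + geometric — a
hard 5-min floor, so simulated inactive time is *exactly* what the
scorer recovers (the identity every recovery test rests on; the single
exception is a final bout truncated by the end of the recording). Wake
minutes emit `1 + Poisson(λ)` counts (λ = 1.5 min⁻¹), so wakefulness
can never be mis-scored as sleep.

A circadian gate pins the stationary sleep fraction to

```
f(zt) = 0.62 + 0.18·cos(2π(zt − 18)/24)
        − 0.30·N(zt; 1.0, 1.8) − 0.35·N(zt; 11.0, 1.8)
```

(wrapped Gaussians, clipped to [0.05, 0.95]): consolidated night sleep
peaking around ZT18, wake peaks after lights-on and before lights-off,
and a midday siesta — the classic bimodal fly profile. Mean sleep-bout
length is `5 + 40·f` minutes, and the mean wake bout follows from the
stationarity constraint `μ_w = μ_s (1 − f)/f`. These defaults give
roughly 700–850 min of daily sleep with low sleep in the early morning
and pre-dusk hours; they were fixed once as a qualitatively realistic
female-fly profile. A mild sleep-debt homeostat (mechanistic mode only)
raises effective propensity after enforced wakefulness: debt grows
1 min per wake minute, is repaid at 1.5 min per sleep minute, and
shifts `f` toward its ceiling with weight 0.003 per debt minute.

During SD windows each minute independently forces wakefulness with
probability η (default 0.99 ≈ three stimuli per minute); at that
efficacy a 5-min unforced run is essentially impossible, so scored
SD-window sleep is near zero and deprivation efficiency concentrates
near 1, as the inclusion filter presumes.

**Gain injection.** In `gain_injection` mode the homeostat is off and
each rebound window runs a constant-fraction process calibrated so the
*expected scored sleep* in the window equals `B(z) + g(z)`, where
`g` is the injected gain profile and `B(z)` the model's expected
baseline sleep for that clock window. `B` is estimated once per
configuration from a fixed-internal-seed reference cohort (150 flies ×
2 post-burn-in days); the window fraction is then solved by monotone
bisection against a fixed-seed window simulator that starts awake (as
flies do after stimulation) and scores with the 5-min rule, which
absorbs the start-of-window edge bias an analytic stationary
calculation would miss. Consequently the pipeline's expected measured
gain equals `g(z)` up to estimator noise of a few minutes. The default
profile anchors the morning and evening values at 133 min (ZT1.5) and
51 min (ZT9.5) — the canonical >2× contrast — with the remaining
anchors (110 at ZT5.5, 35 at ZT13.5, 20 at ZT17.5, 40 at ZT21.5) chosen
once as a plausible smooth curve that stays feasible against the night
ceiling `g ≤ 270 − B`.

Each fly consumes an independent random substream derived from
`(seed, fly_index)`, so enlarging a cohort never perturbs existing
flies.

**What the generator does and does not emulate.** It reproduces the
features the pipeline measures — bout-structured sleep, bimodal
circadian gating, near-complete deprivation, time-of-day-dependent
rebound — but not biophysics: no arousal-threshold dynamics, no
stimulus habituation, no stress effects of repeated vibration, no
inter-fly parameter heterogeneity beyond sampling noise, and geometric
rather than heavy-tailed bout distributions. Passing recovery tests
therefore demonstrates that the *analysis* is correct and unbiased
under known ground truth, not that real flies obey this process.

## Problem sizes and numerical choices

Test and acceptance runs use 32-fly cohorts over the 11-day full
protocol (the study's cohort size), 10 replicate seeds for recovery
checks, 150 × 2 fly-days for baseline estimation, and 512 replicates ×
16 bisection iterations (common random numbers) for injection
calibration — sizes at which estimator bias is a few minutes against a
±3 SEM (≈ 15–20 min) acceptance band. The type-I-error check of the
paired test uses 2,000 replicates of n = 32 gains drawn from identical
morning/evening injected window processes with matched baselines;
exchangeability makes that null exact without simulating thousands of
full protocols. Interpolation, scheduling, and scoring are exact
integer/array operations with no tolerances beyond float round-off.

## Known limitations

- DAM dialect is fixed to the common 10-metadata + 32-channel
  single-beam layout; sub-minute or multi-beam monitors are out of scope.
- Invalid-status records are tolerated only at recording edges;
  interior dropouts are a hard error rather than an imputation problem.
- The DD analysis relabels ZT as CT assuming a 24.0 h period; strongly
  non-24 h mutants would need phase re-estimation upstream.
- Baseline references come from two days; flies with atypical baseline
  days propagate that noise into lost/gain estimates (as in the real
  protocol).
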