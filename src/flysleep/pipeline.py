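"""End-to-end run: (simulate | read DAM) → score → metrics → stats → files.

A run writes, under the output directory:

* ``metrics.csv``      — per fly × episode homeostasis metrics,
* ``summary.json``     — mean ± SEM sleep gain per rebound-onset ZT,
* ``heatmap.csv``      — rebound heatmap matrix (+ observed mask),
* ``baseline_profile.csv`` — baseline sleep per 30-min clock bin,
* ``heatmap.png``      — rendered rebound/baseline heatmap,
* ``stats.json``       — matched pair, paired test, trend regression,
* ``manifest.json``    — seed, config hash, package + library versions.

Identical config and seed produce byte-identical metrics CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dam import LightSchedule, read_dam
from .rebound import apply_efficiency_filter, cohort_metrics, percent_recovered
from .schedule import SSDSchedule, make_abridged_ssd, make_full_ssd
from .scoring import score_sleep
from .simulate import SimConfig, simulate_cohort
from .stats import (
    baseline_heatmap,
    gain_trend,
    match_morning_evening,
    paired_comparison,
    rebound_heatmap,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    # input: either DAM files or a simulation
    dam_paths: list[str] = field(default_factory=list)
    lights_on: float = 8.0
    light_mode: str = "LD"
    simulate: bool = True
    sim: SimConfig | None = None
    # protocol
    schedule_mode: str = "full"        # full | abridged
    first_onset_zt: float = 4.5
    schedule_json: str | None = None   # overrides schedule_mode when set
    # analysis
    efficiency_threshold: float = 0.9
    filter_per: str = "fly"
    match_tol_baseline: float = 45.0
    match_tol_lost: float = 45.0
    bin_minutes: int = 30

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def build_schedule(cfg: RunConfig) -> SSDSchedule:
    if cfg.schedule_json:
        return SSDSchedule.from_json(Path(cfg.schedule_json))
    if cfg.schedule_mode == "full":
        return make_full_ssd(first_onset_zt=cfg.first_onset_zt)
    if cfg.schedule_mode == "abridged":
        return make_abridged_ssd()
    raise ValueError(f"unknown schedule mode {cfg.schedule_mode!r}")


def _load_table(cfg: RunConfig, schedule: SSDSchedule):
    if cfg.simulate:
        sim = cfg.sim if cfg.sim is not None else SimConfig()
        sim.seed = cfg.seed
        return simulate_cohort(sim, schedule)
    if not cfg.dam_paths:
        raise ValueError("no DAM inputs and simulate=False")
    tables = []
    ls = LightSchedule(lights_on=cfg.lights_on, mode=cfg.light_mode)
    for p in cfg.dam_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"DAM file not found: {p}")
        tables.append(read_dam(p, ls))
    if len(tables) == 1:
        return tables[0]
    base = tables[0]
    counts = np.vstack([t.counts for t in tables])
    fly_ids = [fid for t in tables for fid in t.fly_ids]
    from .dam import ActivityTable

    return ActivityTable(
        counts=counts, fly_ids=fly_ids, zt0=base.zt0, start=base.start, mode=base.mode
    )


def _plot_heatmap(hm, baseline_profile, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(6, 7), height_ratios=[5, 1], constrained_layout=True
    )
    im = ax0.imshow(
        hm.values, aspect="auto", cmap="viridis", vmin=0, vmax=hm.bin_minutes,
        extent=[0, hm.values.shape[1] * hm.bin_minutes, hm.rows_zt[-1], hm.rows_zt[0]],
    )
    ax0.set_xlabel("minutes after SD end")
    ax0.set_ylabel("rebound onset (ZT)")
    ax0.set_title("rebound sleep (min per bin)")
    fig.colorbar(im, ax=ax0)
    ax1.imshow(
        baseline_profile.values[np.newaxis, :], aspect="auto", cmap="viridis",
        vmin=0, vmax=baseline_profile.bin_minutes, extent=[0, 24, 0, 1],
    )
    ax1.set_yticks([])
    ax1.set_xlabel("ZT (h)")
    ax1.set_title("baseline sleep")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a results dictionary and writes files."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    schedule = build_schedule(cfg)
    log.info("schedule: %s, %d episodes", schedule.mode, schedule.n_episodes)
    table = _load_table(cfg, schedule)
    series = score_sleep(table)
    metrics = cohort_metrics(series, schedule)
    metrics["percent_recovered"] = percent_recovered(metrics)
    filt = apply_efficiency_filter(
        metrics, threshold=cfg.efficiency_threshold, per=cfg.filter_per
    )
    log.info("efficiency filter: %d/%d flies retained", len(filt.retained), table.n_flies)
    retained_metrics = metrics[metrics["fly_id"].isin(filt.retained)]

    # per-onset summaries
    rows = []
    for e in schedule.episodes:
        sel = retained_metrics[retained_metrics["episode_index"] == e.index]
        rows.append(
            {
                "episode_index": e.index,
                "onset_zt": e.onset_zt,
                "mean_gain": sel["sleep_gain"].mean(),
                "sem_gain": sel["sleep_gain"].sem(),
                "mean_lost": sel["sleep_lost"].mean(),
                "mean_baseline_rebound": sel["baseline_sleep_rebound_window"].mean(),
                "n": len(sel),
            }
        )
    summary = pd.DataFrame(rows)

    hm = rebound_heatmap(series, schedule, retained=filt.retained, bin_minutes=cfg.bin_minutes)
    base_prof = baseline_heatmap(series, schedule.baseline_days, cfg.bin_minutes)

    pair = match_morning_evening(
        summary, tol_baseline=cfg.match_tol_baseline, tol_lost=cfg.match_tol_lost
    )
    stats_out: dict = {"matched_pair": asdict(pair)}
    if pair.found:
        gm = retained_metrics[np.isclose(retained_metrics["onset_zt"], pair.morning_zt)]
        ge = retained_metrics[np.isclose(retained_metrics["onset_zt"], pair.evening_zt)]
        gm = gm.set_index("fly_id")["sleep_gain"]
        ge = ge.set_index("fly_id")["sleep_gain"]
        common = gm.index.intersection(ge.index)
        res = paired_comparison(gm[common].to_numpy(), ge[common].to_numpy())
        stats_out["paired_gain_test"] = asdict(res)
    trend = gain_trend(summary["mean_gain"].to_numpy(), summary["episode_index"].to_numpy())
    stats_out["gain_trend"] = asdict(trend)

    # outputs
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.6g")
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6g")
    (out / "summary.json").write_text(
        json.dumps(
            {f"{r['onset_zt']:.2f}": {"mean": None if pd.isna(r["mean_gain"]) else r["mean_gain"],
                                       "sem": None if pd.isna(r["sem_gain"]) else r["sem_gain"],
                                       "n": int(r["n"])}
             for r in rows},
            indent=2,
        )
    )
    hm.to_frame().to_csv(out / "heatmap.csv", index=False, float_format="%.6g")
    pd.DataFrame(
        {"zt": base_prof.bin_zts, "sleep_min": base_prof.values}
    ).to_csv(out / "baseline_profile.csv", index=False, float_format="%.6g")
    (out / "stats.json").write_text(json.dumps(stats_out, indent=2, default=float))
    schedule.to_json(out / "schedule.json")
    try:
        _plot_heatmap(hm, base_prof, out / "heatmap.png")
    except Exception as exc:  # plotting is convenience, values are the contract
        log.warning("heatmap rendering failed: %s", exc)

    manifest = {
        "package": "flysleep",
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "config_hash": cfg.config_hash(),
        "n_flies": table.n_flies,
        "n_retained": len(filt.retained),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "table": table,
        "series": series,
        "schedule": schedule,
        "metrics": metrics,
        "filter": filt,
        "summary": summary,
        "heatmap": hm,
        "baseline_profile": base_prof,
        "stats": stats_out,
    }
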