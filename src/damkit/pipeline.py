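"""Full-analysis orchestration: config file -> CSV tables, plots, manifest.

A run is reproducible from the config file plus the input monitor files
alone: every analysis stage (I/O validation, layout, dead-fly exclusion,
activity, sleep, circadian) is driven off the AnalysisConfig, all tables
are written as UTF-8 comma-separated CSV with ISO-8601 dates, and plots
carry no embedded timestamps, so re-running the same config reproduces
byte-identical CSVs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dc_field
from datetime import date, time
from typing import Any, Mapping

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import activity as act
from . import circadian as circ
from . import sleep as slp
from . import viability as via
from .experiment import (Condition, ExperimentLayout, LightCalendar, LD, DD,
                         SettingsConflictError, extract_fly_series)
from .io import MonitorData, read_monitor_file


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    monitor_paths: list[str]
    interval_minutes: float
    conditions: list[dict[str, Any]]    # name, color, monitor, channels
    ld_start: date | None = None
    ld_end: date | None = None
    dd_start: date | None = None
    dd_end: date | None = None
    light_onset: time = time(6, 0)
    day_length_hours: float = 12.0
    analyze: str = "both"               # "LD" | "DD" | "both"
    dead_threshold: float = 50.0
    dead_mode: str = "exclude"
    sleep_window_minutes: int = 5
    profile_bin_minutes: float = 30.0
    actogram_bin_minutes: float = 30.0
    actogram_style: str = "double"
    period_min_h: float = 18.0
    period_max_h: float = 30.0
    period_resolution_h: float = 0.1
    alpha: float = 0.05
    period_correction: str = "sidak"
    strength_threshold: float = 1.0
    plot_width: float = 8.0
    plot_height: float = 4.0
    plot_ymax: float | None = None
    output_dir: str = "damkit_output"

    def calendar(self) -> LightCalendar:
        cal = LightCalendar(self.ld_start, self.ld_end,
                            self.dd_start, self.dd_end,
                            self.light_onset, self.day_length_hours)
        if self.analyze not in ("LD", "DD", "both"):
            raise SettingsConflictError(
                f"analyze must be LD, DD, or both, got {self.analyze!r}")
        if self.analyze in ("LD", "both") and self.ld_start is None:
            raise SettingsConflictError("LD analysis requested but no LD dates given")
        if self.analyze in ("DD", "both") and self.dd_start is None:
            raise SettingsConflictError("DD analysis requested but no DD dates given")
        if self.analyze == "LD":
            cal = LightCalendar(self.ld_start, self.ld_end, None, None,
                                self.light_onset, self.day_length_hours)
        elif self.analyze == "DD":
            cal = LightCalendar(None, None, self.dd_start, self.dd_end,
                                self.light_onset, self.day_length_hours)
        return cal

    def layout(self) -> ExperimentLayout:
        conds = [Condition(c["name"], c.get("color", "#1f77b4"),
                           tuple((c["monitor"], int(ch)) for ch in c["channels"]))
                 for c in self.conditions]
        return ExperimentLayout(conds, self.calendar(),
                                self.interval_minutes, self.dead_threshold)


def _parse_date(v: Any) -> date | None:
    if v is None:
        return None
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


def load_config(path: str | os.PathLike) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    onset = raw.get("light_onset", "06:00")
    if isinstance(onset, time):
        pass
    else:
        onset = time.fromisoformat(str(onset))
    pg = raw.get("periodogram", {})
    return AnalysisConfig(
        monitor_paths=[str(p) for p in raw["monitors"]],
        interval_minutes=float(raw["interval_minutes"]),
        conditions=list(raw["conditions"]),
        ld_start=_parse_date(raw.get("ld_start")),
        ld_end=_parse_date(raw.get("ld_end")),
        dd_start=_parse_date(raw.get("dd_start")),
        dd_end=_parse_date(raw.get("dd_end")),
        light_onset=onset,
        day_length_hours=float(raw.get("day_length_hours", 12.0)),
        analyze=str(raw.get("analyze", "both")),
        dead_threshold=float(raw.get("dead_threshold", 50.0)),
        dead_mode=str(raw.get("dead_mode", "exclude")),
        sleep_window_minutes=int(raw.get("sleep_window_minutes", 5)),
        profile_bin_minutes=float(raw.get("profile_bin_minutes", 30.0)),
        actogram_bin_minutes=float(raw.get("actogram_bin_minutes", 30.0)),
        actogram_style=str(raw.get("actogram_style", "double")),
        period_min_h=float(pg.get("min_h", 18.0)),
        period_max_h=float(pg.get("max_h", 30.0)),
        period_resolution_h=float(pg.get("resolution_h", 0.1)),
        alpha=float(pg.get("alpha", 0.05)),
        period_correction=str(pg.get("correction", "sidak")),
        strength_threshold=float(pg.get("strength_threshold", 1.0)),
        plot_width=float(raw.get("plot_width", 8.0)),
        plot_height=float(raw.get("plot_height", 4.0)),
        plot_ymax=raw.get("plot_ymax"),
        output_dir=str(raw.get("output_dir", "damkit_output")),
    )


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, outdir: str, name: str,
               manifest: list[str], index: bool = False) -> None:
    path = os.path.join(outdir, name)
    df.to_csv(path, index=index)
    manifest.append(name)


def _save_fig(fig, outdir: str, name: str, manifest: list[str]) -> None:
    fig.savefig(os.path.join(outdir, name), metadata={"Software": None})
    plt.close(fig)
    manifest.append(name)


def run_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Execute the whole pipeline; return the output manifest.

    Settings conflicts (overlapping regimes, unknown monitors, bad
    toggles) are raised before any monitor file is analyzed.  Exit
    contract for the CLI: no fatal issue <=> manifest written.
    """
    layout = config.layout()  # validates settings first
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    manifest: list[str] = []
    log: list[str] = ["settings:"]
    for k, v in sorted(vars(config).items()):
        log.append(f"  {k}: {v}")

    monitors: dict[str, MonitorData] = {}
    for p in config.monitor_paths:
        m = read_monitor_file(p, config.interval_minutes)
        monitors[m.monitor_id] = m
        log.append(f"monitor {m.monitor_id}: {len(m.records)} records, "
                   f"{len(m.warnings)} warning(s)")
        for issue in m.issues:
            log.append(f"  {issue}")

    flies = extract_fly_series(monitors, layout)
    log.append(f"extracted {len(flies)} fly series")

    report = via.assess_viability(flies, layout)
    alive = via.apply_viability(flies, report, layout.calendar, config.dead_mode)
    dead_rows = [{"fly_id": f, "condition": layout.condition_of(f),
                  "alive": v.alive,
                  "first_dead_day": v.first_dead_day,
                  "min_daily_total": v.min_daily_total}
                 for f, v in report.flies.items()]
    _write_csv(pd.DataFrame(dead_rows), outdir, "dead_flies.csv", manifest)
    _write_csv(report.condition_table.reset_index(), outdir,
               "condition_counts.csv", manifest)
    log.append(f"dead flies excluded: {len(report.dead_ids())} "
               f"({config.dead_mode} mode)")

    day_table = act.fly_day_table(alive, layout.calendar, config.interval_minutes)
    dt = day_table.copy()
    dt["condition"] = dt["fly_id"].map(layout.condition_of)
    _write_csv(dt, outdir, "daily_locomotor_activity_by_fly.csv", manifest)

    for regime in (LD, DD):
        if config.analyze not in (regime, "both"):
            log.append(f"{regime} outputs skipped (analyze={config.analyze})")
            continue
        phases = ("all", "day", "night") if regime == LD else ("all",)
        rows = []
        for phase in phases:
            summary = act.condition_daily_activity(day_table, layout,
                                                   regime, phase)
            t = summary.table.reset_index()
            t.insert(1, "phase", phase)
            rows.append(t)
        _write_csv(pd.concat(rows, ignore_index=True), outdir,
                   f"condition_summary_{regime}.csv", manifest)

    by_day = act.activity_by_day(day_table, layout)
    _write_csv(by_day, outdir, "activity_by_day.csv", manifest)

    profiles = act.activity_profile(alive, layout, config.profile_bin_minutes,
                                    mode="full_experiment")
    long = []
    for pr in profiles:
        t = pr.table.reset_index()
        t.insert(0, "condition", pr.condition)
        long.append(t)
    if long:
        _write_csv(pd.concat(long, ignore_index=True), outdir,
                   "activity_profile.csv", manifest)

    # --- sleep -------------------------------------------------------------
    states = {f: slp.detect_sleep(s, config.interval_minutes,
                                  config.sleep_window_minutes, fly_id=f)
              for f, s in alive.items()}
    sp = slp.sleep_profile(states, layout, config.profile_bin_minutes)
    sp_long = []
    for cond, tbl in sp.items():
        t = tbl.reset_index()
        t.insert(0, "condition", cond)
        sp_long.append(t)
    if sp_long:
        _write_csv(pd.concat(sp_long, ignore_index=True), outdir,
                   "sleep_profile.csv", manifest)
    sleep_rows, bout_rows = [], []
    for f, st in states.items():
        summ = slp.sleep_summary(st, layout.calendar).reset_index()
        summ.insert(0, "fly_id", f)
        summ.insert(1, "condition", layout.condition_of(f))
        sleep_rows.append(summ)
        ab = act.activity_bouts(alive[f], layout.calendar,
                                config.interval_minutes)
        sb = slp.sleep_bouts(st, layout.calendar)
        merged = ab.join(sb, lsuffix="_activity", rsuffix="_sleep",
                         how="outer").reset_index()
        merged.insert(0, "fly_id", f)
        merged.insert(1, "condition", layout.condition_of(f))
        bout_rows.append(merged)
    if sleep_rows:
        _write_csv(pd.concat(sleep_rows, ignore_index=True), outdir,
                   "sleep_day_night_by_fly.csv", manifest)
        _write_csv(pd.concat(bout_rows, ignore_index=True), outdir,
                   "bout_stats_by_fly.csv", manifest)

    # --- circadian (DD) ----------------------------------------------------
    results = []
    if config.analyze in (DD, "both") and config.dd_start is not None:
        span_h = ((config.dd_end - config.dd_start).days + 1) * 24
        if span_h < circ.MIN_CYCLES * config.period_max_h:
            log.append("periodogram skipped: DD span too short for "
                       f"{circ.MIN_CYCLES} cycles of {config.period_max_h} h")
        else:
            for f, s in alive.items():
                in_dd = pd.Series(s.index.date, index=s.index).apply(
                    lambda d: config.dd_start <= d <= config.dd_end)
                dd_series = s[in_dd.to_numpy()]
                if dd_series.empty:
                    continue
                results.append(circ.chi_square_periodogram(
                    dd_series, config.interval_minutes,
                    (config.period_min_h, config.period_max_h),
                    config.period_resolution_h, config.alpha,
                    config.strength_threshold, config.period_correction,
                    fly_id=f))
            if results:
                per_rows = []
                for r in results:
                    per_rows.append(pd.DataFrame({
                        "fly_id": r.fly_id, "period_h": r.periods_h,
                        "Q": r.Q, "S": r.S}))
                _write_csv(pd.concat(per_rows, ignore_index=True), outdir,
                           "periodogram_by_fly.csv", manifest)
                _write_csv(pd.DataFrame(
                    [{"fly_id": r.fly_id,
                      "condition": layout.condition_of(r.fly_id),
                      "peak_period_h": r.peak_period_h,
                      "rhythm_strength": r.rhythm_strength,
                      "rhythmic": r.rhythmic} for r in results]),
                    outdir, "circadian_period_by_fly.csv", manifest)
                rhythmic, arrhythmic = circ.filter_arrhythmic(
                    results, config.strength_threshold)
                log.append(f"rhythmic flies: {len(rhythmic)}/{len(results)}")
                if rhythmic:
                    _write_csv(circ.aggregate_periodogram(rhythmic), outdir,
                               "mean_periodogram.csv", manifest)

    # actograms: one aggregate per condition plus per-fly matrices on request
    for cond in layout.conditions:
        sub = {f: s for f, s in alive.items()
               if layout.condition_of(f) == cond.name}
        if not sub:
            continue
        for aggregate in ("mean", "median"):
            mat = circ.build_actogram(sub, layout.calendar,
                                      config.interval_minutes,
                                      config.actogram_bin_minutes,
                                      config.actogram_style, aggregate)
            t = mat.matrix.reset_index().melt(id_vars="day",
                                              var_name="bin_start_h",
                                              value_name="value")
            _write_csv(t.dropna(), outdir,
                       f"actogram_{cond.name}_{aggregate}.csv", manifest)

    _plots(config, layout, day_table, profiles, sp, results, alive,
           outdir, manifest, log)

    log.append(f"outputs: {len(manifest)} files")
    with open(os.path.join(outdir, "run_log.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(log) + "\n")
    manifest.append("run_log.txt")
    man = {"output_dir": outdir, "files": sorted(manifest)}
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(man, fh, indent=2)
    return man


def _plots(config, layout, day_table, profiles, sleep_profiles, pg_results,
           alive, outdir, manifest, log) -> None:
    size = (config.plot_width, config.plot_height)
    colors = {c.name: c.color for c in layout.conditions}

    regime = LD if config.analyze in (LD, "both") else DD
    summary = act.condition_daily_activity(day_table, layout, regime, "all")
    fig, ax = plt.subplots(figsize=size)
    t = summary.table
    ax.bar(t.index, t["mean"], yerr=t["sem"],
           color=[colors.get(c, "#1f77b4") for c in t.index], capsize=4)
    ax.set_ylabel(f"mean daily counts ({regime})")
    if config.plot_ymax:
        ax.set_ylim(0, config.plot_ymax)
    _save_fig(fig, outdir, "daily_activity.png", manifest)

    if profiles:
        fig, ax = plt.subplots(figsize=size)
        for pr in profiles:
            tb = pr.table
            ax.plot(tb.index, tb["mean"], label=pr.condition,
                    color=colors.get(pr.condition))
            ax.fill_between(tb.index, tb["mean"] - tb["sem"],
                            tb["mean"] + tb["sem"], alpha=0.25,
                            color=colors.get(pr.condition))
        ax.set_ylabel(f"counts / {config.profile_bin_minutes:g} min")
        ax.legend()
        _save_fig(fig, outdir, "activity_profile.png", manifest)

    if sleep_profiles:
        fig, ax = plt.subplots(figsize=size)
        for cond, tb in sleep_profiles.items():
            ax.plot(tb.index, tb["mean"], label=cond, color=colors.get(cond))
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("sleep fraction")
        ax.legend()
        _save_fig(fig, outdir, "sleep_profile.png", manifest)

    if pg_results:
        rhythmic, _ = circ.filter_arrhythmic(pg_results,
                                             config.strength_threshold)
        if rhythmic:
            agg = circ.aggregate_periodogram(rhythmic)
            fig, ax = plt.subplots(figsize=size)
            ax.plot(agg["period_h"], agg["mean_Q"], label="mean Q")
            ax.plot(agg["period_h"], agg["S"], "--", label="significance")
            ax.set_xlabel("period (h)")
            ax.set_ylabel("Q")
            ax.legend()
            _save_fig(fig, outdir, "mean_periodogram.png", manifest)

    for cond in layout.conditions:
        sub = {f: s for f, s in alive.items()
               if layout.condition_of(f) == cond.name}
        if not sub:
            continue
        mat = circ.build_actogram(sub, layout.calendar,
                                  config.interval_minutes,
                                  config.actogram_bin_minutes,
                                  config.actogram_style, "mean")
        fig, ax = plt.subplots(figsize=(size[0], max(2.0, 0.4 * len(mat.matrix))))
        ax.imshow(np.ma.masked_invalid(mat.matrix.to_numpy()),
                  aspect="auto", cmap="Greys", interpolation="nearest")
        ax.set_xlabel("hours since light onset")
        ax.set_ylabel("day")
        ax.set_title(f"{cond.name} ({mat.style})")
        _save_fig(fig, outdir, f"actogram_{cond.name}.png", manifest)
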