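"""Locomotor-activity statistics.

Condition summaries aggregate fly-level first: each fly contributes its own
mean daily total (or its own per-bin mean), and the condition mean and SEM
are taken across flies, so flies observed on unequal numbers of days carry
equal weight and the SEM measures between-individual variability.

An *activity bout* is a maximal run of consecutive readings with count > 0;
its length is the run length times the acquisition interval.  A bout that
spans an experimental-day boundary is assigned to the day containing its
first reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .experiment import (ExperimentLayout, LightCalendar, LD, bin_series,
                         label_index)


def runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as (start, length) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def sem(values: np.ndarray) -> float:
    """Standard error of the mean across flies; 0 is returned (flagged by
    n == 1 in the caller's output) when a single fly gives no spread."""
    v = np.asarray(values, dtype=float)
    if v.size <= 1:
        return 0.0
    return float(np.std(v, ddof=1) / np.sqrt(v.size))


# ---------------------------------------------------------------------------
# per-fly per-day bookkeeping
# ---------------------------------------------------------------------------

def fly_day_table(fly_series: Mapping[str, pd.Series],
                  calendar: LightCalendar,
                  interval_minutes: float) -> pd.DataFrame:
    """Long table: one row per fly per experimental day.

    Columns: fly_id, day, regime, complete, total, day_total, night_total.
    Phase totals are only populated on LD days (phase is undefined in DD).
    """
    expected = int(round(1440 / interval_minutes))
    rows = []
    for fid, s in fly_series.items():
        if s.empty:
            continue
        labels = label_index(s.index, calendar)
        df = pd.DataFrame({"x": s.to_numpy(dtype=float),
                           "day": labels["day"].to_numpy(),
                           "regime": labels["regime"].to_numpy(),
                           "phase": labels["phase"].to_numpy()})
        for day, grp in df.groupby("day", sort=True):
            regime = grp["regime"].iloc[0]
            is_day = grp["phase"] == "day"
            rows.append({
                "fly_id": fid,
                "day": day,
                "regime": regime,
                "complete": len(grp) == expected,
                "total": float(grp["x"].sum()),
                "day_total": float(grp.loc[is_day, "x"].sum()) if regime == LD else np.nan,
                "night_total": float(grp.loc[~is_day, "x"].sum()) if regime == LD else np.nan,
            })
    return pd.DataFrame(rows, columns=["fly_id", "day", "regime", "complete",
                                       "total", "day_total", "night_total"])


# ---------------------------------------------------------------------------
# condition summaries
# ---------------------------------------------------------------------------

@dataclass
class ActivitySummary:
    """Condition-level daily-activity summary for one regime/phase scope."""

    regime: str
    phase: str  # "all" | "day" | "night"
    per_fly: pd.Series          # fly_id -> fly mean daily total
    table: pd.DataFrame         # index=condition; mean, sem, n


_PHASE_COL = {"all": "total", "day": "day_total", "night": "night_total"}


def condition_daily_activity(day_table: pd.DataFrame,
                             layout: ExperimentLayout,
                             regime: str = LD,
                             phase: str = "all") -> ActivitySummary:
    """Mean daily activity per condition (mean of fly means, SEM across flies).

    Only complete days in the requested regime contribute.  An empty
    condition yields n=0 and an undefined (NaN) mean rather than an error.
    """
    col = _PHASE_COL[phase]
    sub = day_table[(day_table["regime"] == regime) & day_table["complete"]]
    per_fly = sub.groupby("fly_id")[col].mean()
    rows = []
    for cond in layout.conditions:
        vals = per_fly[[f for f in per_fly.index
                        if layout.condition_of(f) == cond.name]]
        n = len(vals)
        rows.append({"condition": cond.name,
                     "mean": float(vals.mean()) if n else np.nan,
                     "sem": sem(vals.to_numpy()) if n else np.nan,
                     "n": n})
    return ActivitySummary(regime, phase, per_fly,
                           pd.DataFrame(rows).set_index("condition"))


def activity_by_day(day_table: pd.DataFrame,
                    layout: ExperimentLayout) -> pd.DataFrame:
    """Per-condition per-day mean daily total with SEM across flies.

    Long frame: condition, day, regime, mean, sem, n.
    """
    sub = day_table[day_table["complete"]].copy()
    sub["condition"] = sub["fly_id"].map(layout.condition_of)
    rows = []
    for (cond, day), grp in sub.groupby(["condition", "day"], sort=True):
        rows.append({"condition": cond, "day": day,
                     "regime": grp["regime"].iloc[0],
                     "mean": float(grp["total"].mean()),
                     "sem": sem(grp["total"].to_numpy()),
                     "n": len(grp)})
    return pd.DataFrame(rows, columns=["condition", "day", "regime",
                                       "mean", "sem", "n"])


# ---------------------------------------------------------------------------
# activity profiles
# ---------------------------------------------------------------------------

@dataclass
class ActivityProfile:
    """Mean +/- SEM counts per bin for one condition."""

    condition: str
    mode: str                    # "full_experiment" | "ld_average"
    bin_minutes: float
    table: pd.DataFrame          # bin axis; mean, sem, n


def _per_fly_bins(fly_series: Mapping[str, pd.Series],
                  layout: ExperimentLayout,
                  bin_minutes: float) -> dict[str, pd.Series]:
    return {fid: bin_series(s, bin_minutes, layout.interval_minutes,
                            statistic="sum",
                            anchor=layout.calendar.light_onset)
            for fid, s in fly_series.items()}


def activity_profile(fly_series: Mapping[str, pd.Series],
                     layout: ExperimentLayout,
                     bin_minutes: float,
                     mode: str = "full_experiment") -> list[ActivityProfile]:
    """Binned activity profiles per condition.

    ``full_experiment`` gives mean +/- SEM counts per bin across flies over
    the whole analyzed span (bin axis = bin start timestamps).
    ``ld_average`` additionally folds all complete LD days onto a 24-h
    time-of-day axis anchored at light onset (bin axis = hours since onset).
    """
    if mode not in ("full_experiment", "ld_average"):
        raise ValueError(f"unknown profile mode {mode!r}")
    cal = layout.calendar
    binned = _per_fly_bins(fly_series, layout, bin_minutes)
    profiles = []
    for cond in layout.conditions:
        ids = [f for f in binned if layout.condition_of(f) == cond.name]
        if not ids:
            continue
        if mode == "full_experiment":
            wide = pd.DataFrame({f: binned[f] for f in ids})
            tbl = pd.DataFrame({
                "mean": wide.mean(axis=1),
                "sem": wide.apply(lambda r: sem(r.dropna().to_numpy()), axis=1),
                "n": wide.notna().sum(axis=1)})
            tbl.index.name = "bin_start"
        else:
            per_fly = {}
            for f in ids:
                b = binned[f]
                labels = label_index(pd.DatetimeIndex(b.index), cal)
                ld_days = labels[labels["regime"] == LD]["day"]
                counts_per_day = ld_days.groupby(ld_days.to_numpy()).size()
                full = set(counts_per_day[counts_per_day ==
                                          int(round(1440 / bin_minutes))].index)
                keep = labels["day"].isin(full) & (labels["regime"] == LD)
                b = b[keep.to_numpy()]
                if b.empty:
                    continue
                onset_min = cal.light_onset.hour * 60 + cal.light_onset.minute
                tod = (b.index.hour * 60 + b.index.minute - onset_min) % 1440
                per_fly[f] = b.groupby(tod / 60.0).mean()
            if not per_fly:
                raise ValueError(
                    f"condition {cond.name!r}: no complete LD day available "
                    "for the averaged LD profile")
            wide = pd.DataFrame(per_fly)
            tbl = pd.DataFrame({
                "mean": wide.mean(axis=1),
                "sem": wide.apply(lambda r: sem(r.dropna().to_numpy()), axis=1),
                "n": wide.notna().sum(axis=1)})
            tbl.index.name = "hours_since_onset"
        profiles.append(ActivityProfile(cond.name, mode, bin_minutes, tbl))
    return profiles


# ---------------------------------------------------------------------------
# activity bouts
# ---------------------------------------------------------------------------

def activity_bouts(series: pd.Series, calendar: LightCalendar,
                   interval_minutes: float) -> pd.DataFrame:
    """Per-day activity-bout count and mean length (minutes) for one fly.

    Frame indexed by experimental day with columns ``bout_count`` and
    ``mean_bout_length_min`` (0 with ``bout_count`` 0 on all-quiet days).
    """
    x = series.to_numpy(dtype=float)
    days = label_index(series.index, calendar)["day"].to_numpy()
    all_days = pd.unique(days)
    stats = {d: [] for d in all_days}
    for start, length in runs(x > 0):
        stats[days[start]].append(length * interval_minutes)
    rows = []
    for d in sorted(all_days):
        lens = stats[d]
        rows.append({"day": d, "bout_count": len(lens),
                     "mean_bout_length_min": float(np.mean(lens)) if lens else 0.0})
    return pd.DataFrame(rows).set_index("day")
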