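"""Sleep-state inference and sleep statistics.

Fly sleep is defined behaviorally: any continuous period of locomotor
inactivity (zero beam crossings) lasting at least ``window_minutes``
(5 min by default) counts as sleep.  Every minute inside such a maximal
zero-count run is scored 1 (sleep), every other minute 0 (wake); this
maximal-run thresholding is equivalent to sliding a window of
``window_minutes`` consecutive zero readings along the series and marking
every minute any all-zero window covers, and the equivalence is asserted in
the test suite.

Acquisition intervals finer than one minute are first aggregated to 1-min
sums; intervals between 1 and ``window_minutes`` that divide the window are
scored at native resolution with a window of ``window / interval``
readings.  Runs touching the series boundary are scored by their observed
length (no censoring correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from .activity import runs, sem
from .experiment import ExperimentLayout, LightCalendar, LD, bin_series, label_index

DEFAULT_SLEEP_WINDOW_MIN = 5


@dataclass
class SleepState:
    """Per-fly minute-resolution binary sleep series (1 = sleep)."""

    fly_id: str
    series: pd.Series          # minute-indexed int8 0/1
    window_minutes: int
    source_interval_minutes: float


def detect_sleep(series: pd.Series, interval_minutes: float,
                 window_minutes: int = DEFAULT_SLEEP_WINDOW_MIN,
                 fly_id: str | None = None) -> SleepState:
    """Score sleep on one fly's count series.

    A minute is sleep iff it lies inside a maximal run of zero-count
    readings of total duration >= ``window_minutes``.

    Raises
    ------
    ValueError
        If the acquisition interval exceeds the window (too coarse to
        resolve the sleep definition) or does not divide it.
    """
    if interval_minutes > window_minutes:
        raise ValueError(
            f"acquisition interval ({interval_minutes} min) is too coarse for "
            f"sleep analysis with a {window_minutes}-min window")
    if interval_minutes < 1:
        series = bin_series(series, 1.0, interval_minutes, statistic="sum")
        interval_minutes = 1.0
    ratio = window_minutes / interval_minutes
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sleep window ({window_minutes} min) must be a multiple of the "
            f"acquisition interval ({interval_minutes} min)")
    window_readings = int(round(ratio))
    x = series.to_numpy(dtype=float)
    asleep_reading = np.zeros(x.size, dtype=bool)
    for start, length in runs(x == 0):
        if length >= window_readings:
            asleep_reading[start:start + length] = True
    # expand each reading to the minutes it covers
    per_reading = int(round(interval_minutes))
    minute_index = pd.DatetimeIndex([
        t + timedelta(minutes=k)
        for t in series.index for k in range(per_reading)
    ]) if per_reading > 1 else series.index
    minute_values = np.repeat(asleep_reading.astype(np.int8), per_reading)
    out = pd.Series(minute_values, index=minute_index,
                    name=fly_id or series.name)
    return SleepState(fly_id or str(series.name), out,
                      int(window_minutes), float(interval_minutes))


def sleep_summary(state: SleepState, calendar: LightCalendar) -> pd.DataFrame:
    """Per-day sleep minutes, split into day and night phase on LD days.

    Frame indexed by experimental day: total_sleep_min, day_sleep_min,
    night_sleep_min, regime, complete (full 1440 minutes observed).
    """
    labels = label_index(state.series.index, calendar)
    df = pd.DataFrame({"sleep": state.series.to_numpy(dtype=float),
                       "day": labels["day"].to_numpy(),
                       "regime": labels["regime"].to_numpy(),
                       "phase": labels["phase"].to_numpy()})
    rows = []
    for day, grp in df.groupby("day", sort=True):
        regime = grp["regime"].iloc[0]
        is_day = grp["phase"] == "day"
        rows.append({
            "day": day, "regime": regime,
            "total_sleep_min": float(grp["sleep"].sum()),
            "day_sleep_min": float(grp.loc[is_day, "sleep"].sum())
            if regime == LD else np.nan,
            "night_sleep_min": float(grp.loc[~is_day, "sleep"].sum())
            if regime == LD else np.nan,
            "complete": len(grp) == 1440,
        })
    return pd.DataFrame(rows).set_index("day")


def condition_sleep_summary(states: Mapping[str, SleepState],
                            layout: ExperimentLayout,
                            regime: str = LD) -> pd.DataFrame:
    """Condition-level mean +/- SEM of per-fly daily sleep (complete days).

    One row per condition and phase scope (total/day/night).
    """
    per_fly = {}
    for fid, st in states.items():
        summ = sleep_summary(st, layout.calendar)
        summ = summ[(summ["regime"] == regime) & summ["complete"]]
        if summ.empty:
            continue
        per_fly[fid] = summ[["total_sleep_min", "day_sleep_min",
                             "night_sleep_min"]].mean()
    wide = pd.DataFrame(per_fly).T  # fly x scope
    rows = []
    for cond in layout.conditions:
        ids = [f for f in wide.index if layout.condition_of(f) == cond.name]
        sub = wide.loc[ids]
        for col, scope in (("total_sleep_min", "all"), ("day_sleep_min", "day"),
                           ("night_sleep_min", "night")):
            vals = sub[col].dropna().to_numpy() if not sub.empty else np.array([])
            rows.append({"condition": cond.name, "phase": scope,
                         "mean": float(vals.mean()) if vals.size else np.nan,
                         "sem": sem(vals) if vals.size else np.nan,
                         "n": int(vals.size)})
    return pd.DataFrame(rows)


def sleep_profile(states: Mapping[str, SleepState],
                  layout: ExperimentLayout,
                  bin_minutes: float) -> dict[str, pd.DataFrame]:
    """Per-condition mean sleep fraction +/- SEM per bin over the full span.

    Each fly contributes its own per-bin mean (a fraction in [0, 1]);
    condition aggregation is the mean of fly means.
    """
    binned = {fid: bin_series(st.series.astype(float), bin_minutes, 1.0,
                              statistic="mean",
                              anchor=layout.calendar.light_onset)
              for fid, st in states.items()}
    out = {}
    for cond in layout.conditions:
        ids = [f for f in binned if layout.condition_of(f) == cond.name]
        if not ids:
            continue
        wide = pd.DataFrame({f: binned[f] for f in ids})
        tbl = pd.DataFrame({
            "mean": wide.mean(axis=1),
            "sem": wide.apply(lambda r: sem(r.dropna().to_numpy()), axis=1),
            "n": wide.notna().sum(axis=1)})
        tbl.index.name = "bin_start"
        out[cond.name] = tbl
    return out


def sleep_bouts(state: SleepState, calendar: LightCalendar) -> pd.DataFrame:
    """Per-day sleep-bout count and mean length for one fly.

    A sleep bout is a maximal run of sleep minutes; it belongs to the day
    containing its first minute.  By construction no bout is shorter than
    the detection window.
    """
    x = state.series.to_numpy(dtype=np.int8)
    days = label_index(state.series.index, calendar)["day"].to_numpy()
    all_days = pd.unique(days)
    stats = {d: [] for d in all_days}
    for start, length in runs(x == 1):
        stats[days[start]].append(float(length))
    rows = []
    for d in sorted(all_days):
        lens = stats[d]
        rows.append({"day": d, "bout_count": len(lens),
                     "mean_bout_length_min": float(np.mean(lens)) if lens else 0.0})
    return pd.DataFrame(rows).set_index("day")
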