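"""Experiment layout and light-regime time machinery.

An experiment assigns monitor channels to named conditions and declares a
light calendar: a range of LD dates (light:dark entrainment), a range of DD
dates (constant darkness, free run), the clock time of light onset, and the
day length.  Every analysis downstream keys its statistics on
*experimental days*, which run from one light onset to the next (not
midnight to midnight) so that each day contains one full day phase followed
by one full night phase.  In DD the same onset-anchored boundary is kept as
the subjective day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from .io import MonitorData, N_CHANNELS

LD = "LD"
DD = "DD"
EXCLUDED = "excluded"


class SettingsConflictError(ValueError):
    """A conflict in the analysis settings (bad layout, overlapping ranges...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """A named experimental group mapped to monitor channels."""

    name: str
    color: str = "#1f77b4"
    channel_refs: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.channel_refs:
            raise SettingsConflictError(f"condition {self.name!r} has no channels")
        for mon, ch in self.channel_refs:
            if not 1 <= ch <= N_CHANNELS:
                raise SettingsConflictError(
                    f"condition {self.name!r}: channel {ch} outside 1..{N_CHANNELS}")


@dataclass(frozen=True)
class LightCalendar:
    """LD/DD date ranges (inclusive), light onset, and day length."""

    ld_start: date | None = None
    ld_end: date | None = None
    dd_start: date | None = None
    dd_end: date | None = None
    light_onset: time = time(6, 0)
    day_length_hours: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.day_length_hours < 24:
            raise SettingsConflictError(
                f"day_length_hours must be in (0, 24), got {self.day_length_hours}")
        for tag, a, b in (("LD", self.ld_start, self.ld_end),
                          ("DD", self.dd_start, self.dd_end)):
            if (a is None) != (b is None):
                raise SettingsConflictError(f"{tag} range needs both start and end")
            if a is not None and b < a:
                raise SettingsConflictError(f"{tag} range end {b} precedes start {a}")
        if self.ld_start is not None and self.dd_start is not None:
            if self.ld_start <= self.dd_end and self.dd_start <= self.ld_end:
                raise SettingsConflictError(
                    f"LD dates {self.ld_start}..{self.ld_end} overlap DD dates "
                    f"{self.dd_start}..{self.dd_end}; the regimes must not share days")

    def regime_of_date(self, d: date) -> str:
        if self.ld_start is not None and self.ld_start <= d <= self.ld_end:
            return LD
        if self.dd_start is not None and self.dd_start <= d <= self.dd_end:
            return DD
        return EXCLUDED

    @property
    def analyzed_dates(self) -> list[date]:
        out: list[date] = []
        for a, b in ((self.ld_start, self.ld_end), (self.dd_start, self.dd_end)):
            if a is not None:
                out.extend(a + timedelta(days=k) for k in range((b - a).days + 1))
        return sorted(out)


@dataclass
class ExperimentLayout:
    """Conditions plus calendar plus global acquisition settings."""

    conditions: list[Condition]
    calendar: LightCalendar
    interval_minutes: float
    dead_threshold: float = 50.0

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for cond in self.conditions:
            for ref in cond.channel_refs:
                if ref in seen:
                    raise SettingsConflictError(
                        f"channel {ref[0]} ch{ref[1]} assigned to both "
                        f"{seen[ref]!r} and {cond.name!r}")
                seen[ref] = cond.name

    def condition_of(self, fly_id: str) -> str:
        return fly_id.split("_", 1)[0]


def fly_id(condition: str, monitor_id: str, channel: int) -> str:
    return f"{condition}_{monitor_id}_{channel:02d}"


# ---------------------------------------------------------------------------
# time labeling
# ---------------------------------------------------------------------------

def experimental_day(t: datetime, calendar: LightCalendar) -> date:
    """The onset-anchored day containing ``t`` (onset-to-onset boundaries)."""
    return t.date() if t.time() >= calendar.light_onset else t.date() - timedelta(days=1)


def label_reading(t: datetime, calendar: LightCalendar) -> tuple[str, str, date]:
    """Label a timestamp with (regime, phase, experimental_day).

    Regime comes from calendar-date membership in the LD/DD ranges.  Within
    LD, phase is ``day`` iff the time of day lies in
    ``[light_onset, light_onset + day_length_hours)``; in DD and on excluded
    dates the phase is ``none``.
    """
    regime = calendar.regime_of_date(t.date())
    day = experimental_day(t, calendar)
    if regime != LD:
        return regime, "none", day
    onset_min = calendar.light_onset.hour * 60 + calendar.light_onset.minute
    tod_min = t.hour * 60 + t.minute + t.second / 60.0
    since_onset = (tod_min - onset_min) % (24 * 60)
    phase = "day" if since_onset < calendar.day_length_hours * 60 else "night"
    return regime, phase, day


def label_index(index: pd.DatetimeIndex, calendar: LightCalendar) -> pd.DataFrame:
    """Vectorized :func:`label_reading` over a DatetimeIndex."""
    onset_min = calendar.light_onset.hour * 60 + calendar.light_onset.minute
    tod_min = index.hour * 60 + index.minute + index.second / 60.0
    since_onset = (tod_min - onset_min) % (24 * 60)
    dates = pd.Series(index.date, index=index)
    day = dates.where(tod_min >= onset_min,
                      dates - timedelta(days=1))
    regime = dates.map(calendar.regime_of_date)
    phase = pd.Series(np.where(since_onset < calendar.day_length_hours * 60,
                               "day", "night"), index=index)
    phase = phase.where(regime == LD, "none")
    return pd.DataFrame({"regime": regime, "phase": phase, "day": day})


# ---------------------------------------------------------------------------
# fly series extraction
# ---------------------------------------------------------------------------

def extract_fly_series(monitors: Mapping[str, MonitorData],
                       layout: ExperimentLayout) -> dict[str, pd.Series]:
    """One count series per assigned channel, restricted to analyzed dates.

    Fly ids are ``<condition>_<monitor>_<channel>``.  A condition that
    references a monitor that is not loaded is a settings conflict.
    """
    intervals = {m.interval_minutes for m in monitors.values()}
    if len(intervals) > 1:
        raise SettingsConflictError(
            f"monitors disagree on acquisition interval: {sorted(intervals)}; "
            "all monitors in one analysis must share it")
    analyzed = set(layout.calendar.analyzed_dates)
    out: dict[str, pd.Series] = {}
    frames: dict[str, pd.DataFrame] = {}
    for cond in layout.conditions:
        for mon_id, ch in cond.channel_refs:
            if mon_id not in monitors:
                raise SettingsConflictError(
                    f"condition {cond.name!r} references monitor {mon_id!r} "
                    "which is not loaded; add the file or fix the layout")
            if mon_id not in frames:
                frames[mon_id] = monitors[mon_id].counts_frame()
            s = frames[mon_id][ch]
            mask = pd.Series(s.index.date, index=s.index).isin(analyzed)
            s = s[mask.to_numpy()]
            s.name = fly_id(cond.name, mon_id, ch)
            out[s.name] = s
    return out


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_series(x: pd.Series, bin_minutes: float, interval_minutes: float,
               statistic: str = "sum",
               anchor: time | None = None) -> pd.Series:
    """Aggregate a count series into non-overlapping fixed-width bins.

    Bins are aligned to ``anchor`` (a time of day, typically the light
    onset); with no anchor they are aligned to the first timestamp.  Only
    complete bins (``bin_minutes / interval_minutes`` members) are kept, so
    partial leading/trailing bins are dropped.  The returned series is
    indexed by bin start time.
    """
    ratio = bin_minutes / interval_minutes
    if abs(ratio - round(ratio)) > 1e-9 or bin_minutes <= 0:
        raise ValueError(
            f"bin_minutes ({bin_minutes}) must be a positive multiple of the "
            f"acquisition interval ({interval_minutes})")
    per_bin = int(round(ratio))
    if statistic not in ("sum", "mean"):
        raise ValueError(f"statistic must be 'sum' or 'mean', got {statistic!r}")
    if x.empty:
        return pd.Series(dtype=float, name=x.name)
    t0 = x.index[0]
    if anchor is not None:
        origin = datetime.combine(t0.date(), anchor)
        if origin > t0:
            origin -= timedelta(days=1)
    else:
        origin = t0
    offset_min = (x.index - origin).total_seconds() / 60.0
    bin_id = np.floor(offset_min / bin_minutes).astype(np.int64)
    g = x.groupby(bin_id)
    agg = g.sum() if statistic == "sum" else g.mean()
    full = g.size() == per_bin
    agg = agg[full]
    starts = pd.DatetimeIndex([origin + timedelta(minutes=bin_minutes * int(b))
                               for b in agg.index])
    return pd.Series(agg.to_numpy(dtype=float), index=starts, name=x.name)


def complete_days(series: pd.Series, calendar: LightCalendar,
                  interval_minutes: float) -> pd.Series:
    """Per-experimental-day reading counts marked complete/partial.

    A day is complete when it holds the full ``1440 / interval`` readings.
    """
    labels = label_index(series.index, calendar)
    per_day = labels.groupby("day").size()
    expected = int(round(1440 / interval_minutes))
    return per_day == expected
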