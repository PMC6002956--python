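"""Automatic dead-fly identification by a daily activity threshold.

A fly is called dead when its total beam crossings on any *complete*
experimental day fall below the configured threshold; partial first/last
days are never used for death calls because their totals are biased low.
By default a dead fly is excluded from all downstream statistics for the
whole series (``mode="exclude"``); ``mode="truncate"`` instead keeps the
days before the first sub-threshold day.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping

import pandas as pd

from .experiment import ExperimentLayout, LightCalendar, label_index


@dataclass(frozen=True)
class FlyViability:
    fly_id: str
    alive: bool
    first_dead_day: date | None
    min_daily_total: float
    daily_totals: pd.Series  # indexed by experimental day, complete days only


@dataclass
class ViabilityReport:
    """Per-fly death calls plus the per-condition head-count table."""

    flies: dict[str, FlyViability]
    condition_table: pd.DataFrame  # index=condition; n_assigned, n_dead, n_analyzed

    def alive_ids(self) -> list[str]:
        return [f for f, v in self.flies.items() if v.alive]

    def dead_ids(self) -> list[str]:
        return [f for f, v in self.flies.items() if not v.alive]


def daily_totals(series: pd.Series, calendar: LightCalendar,
                 interval_minutes: float) -> pd.DataFrame:
    """Total counts per onset-anchored experimental day.

    Returns a frame indexed by day with columns ``total`` and ``complete``
    (whether the day holds the full complement of readings).
    """
    if series.empty:
        raise ValueError("series is empty")
    labels = label_index(series.index, calendar)
    g = series.groupby(labels["day"].to_numpy())
    totals = g.sum()
    expected = int(round(1440 / interval_minutes))
    complete = g.size() == expected
    return pd.DataFrame({"total": totals.astype(float), "complete": complete})


def flag_dead(daily: pd.DataFrame, threshold: float) -> tuple[bool, date | None]:
    """Apply the daily-activity death rule to one fly's daily totals.

    The fly is dead iff ``total < threshold`` on any complete day; the
    first such day is reported.  Returns ``(alive, first_dead_day)``.
    """
    complete = daily[daily["complete"]]
    below = complete.index[complete["total"] < threshold]
    if len(below) == 0:
        return True, None
    return False, min(below)


def assess_viability(fly_series: Mapping[str, pd.Series],
                     layout: ExperimentLayout) -> ViabilityReport:
    """Run the death rule over every fly and build the condition table."""
    flies: dict[str, FlyViability] = {}
    for fid, s in fly_series.items():
        daily = daily_totals(s, layout.calendar, layout.interval_minutes)
        alive, first_dead = flag_dead(daily, layout.dead_threshold)
        complete = daily[daily["complete"]]["total"]
        flies[fid] = FlyViability(
            fid, alive, first_dead,
            float(complete.min()) if len(complete) else float("nan"),
            complete)
    rows = []
    for cond in layout.conditions:
        ids = [f for f in flies if layout.condition_of(f) == cond.name]
        n_dead = sum(1 for f in ids if not flies[f].alive)
        rows.append({"condition": cond.name, "n_assigned": len(ids),
                     "n_dead": n_dead, "n_analyzed": len(ids) - n_dead})
    table = pd.DataFrame(rows).set_index("condition")
    return ViabilityReport(flies, table)


def apply_viability(fly_series: Mapping[str, pd.Series],
                    report: ViabilityReport,
                    calendar: LightCalendar,
                    mode: str = "exclude") -> dict[str, pd.Series]:
    """Drop (or truncate) dead flies from the series map.

    ``exclude`` removes the whole fly; ``truncate`` keeps readings from
    experimental days strictly before the first sub-threshold day.
    """
    if mode not in ("exclude", "truncate"):
        raise ValueError(f"mode must be 'exclude' or 'truncate', got {mode!r}")
    out: dict[str, pd.Series] = {}
    for fid, s in fly_series.items():
        v = report.flies[fid]
        if v.alive:
            out[fid] = s
        elif mode == "truncate":
            days = label_index(s.index, calendar)["day"]
            trimmed = s[(days < v.first_dead_day).to_numpy()]
            if not trimmed.empty:
                out[fid] = trimmed
    return out
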