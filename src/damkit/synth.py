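"""Seeded generator of synthetic DAM monitor data with known ground truth.

Each simulated fly is a FlySpec: an inhomogeneous Poisson beam-crossing
process whose rate oscillates with a programmed period, optionally masked
by the light:dark cycle and optionally dying (rate drops to zero) at a
programmed day's light onset.  The generator emits a fully valid
MonitorData (writable through the monitor-file writer) plus a GroundTruth
table sufficient to score parameter-recovery tests: true period, true
death day, expected mean daily counts, and the programmed zero-rate
(forced-sleep) blocks.

Counts are drawn as ``Poisson(rate * interval)`` from
``numpy.random.default_rng(seed)``, channel by channel in channel order,
so identical (specs, calendar, seed) inputs reproduce identical files
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .experiment import LightCalendar, LD, label_index
from .io import MonitorData, MonitorRecord, N_CHANNELS

WAVEFORMS = ("sinusoid", "square", "crepuscular")


@dataclass(frozen=True)
class FlySpec:
    """Programmed behavior of one simulated fly.

    The instantaneous rate (counts/min) is
    ``max(0, baseline_rate + amplitude * w(t))`` where ``w`` is the chosen
    waveform evaluated at cycle position ``((t - phase_h) mod period_h) /
    period_h``: sinusoid -> sin(2*pi*pos); square -> 1 on the first half
    cycle, 0 on the second; crepuscular -> two Gaussian bumps at the
    quarter points (dawn/dusk peaks).  ``day_active_fraction`` masks LD
    days: the day-phase rate is scaled by ``2 f`` and the night-phase rate
    by ``2 (1 - f)``, so 0.5 means no masking and 1.0 a fully diurnal fly.
    """

    baseline_rate: float = 1.0
    amplitude: float = 0.0
    period_h: float = 24.0
    phase_h: float = 0.0
    waveform: str = "square"
    death_day: date | None = None
    day_active_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"waveform must be one of {WAVEFORMS}")
        if self.baseline_rate < 0 or self.amplitude < 0 or self.period_h <= 0:
            raise ValueError("rates must be >= 0 and period positive")
        if not 0 <= self.day_active_fraction <= 1:
            raise ValueError("day_active_fraction must lie in [0, 1]")

    def rate_at(self, hours: np.ndarray) -> np.ndarray:
        """Unmasked rate (counts/min) at the given hours since time origin."""
        pos = ((hours - self.phase_h) % self.period_h) / self.period_h
        if self.waveform == "sinusoid":
            w = np.sin(2 * np.pi * pos)
        elif self.waveform == "square":
            w = (pos < 0.5).astype(float)
        else:  # crepuscular: dawn and dusk bumps
            sigma = 0.05
            w = (np.exp(-0.5 * ((pos - 0.25) / sigma) ** 2)
                 + np.exp(-0.5 * ((pos - 0.75) / sigma) ** 2))
        return np.maximum(0.0, self.baseline_rate + self.amplitude * w)


ZERO_FLY = FlySpec(baseline_rate=0.0, amplitude=0.0)


@dataclass
class GroundTruth:
    """What the generator programmed, for scoring recovery tests."""

    table: pd.DataFrame          # per channel: period_h, death_day, expected_daily
    zero_blocks: dict[int, list[tuple[datetime, datetime]]]  # forced-sleep runs


def _time_grid(calendar: LightCalendar, interval_minutes: float,
               start_date: date | None, end_date: date | None) -> pd.DatetimeIndex:
    dates = calendar.analyzed_dates
    if not dates and (start_date is None or end_date is None):
        raise ValueError("calendar has no analyzed dates; give start/end dates")
    d0 = start_date or dates[0]
    d1 = end_date or dates[-1]
    t0 = datetime.combine(d0, time(0, 0))
    t1 = datetime.combine(d1 + timedelta(days=1), time(0, 0))
    n = int(round((t1 - t0).total_seconds() / 60.0 / interval_minutes))
    return pd.DatetimeIndex([t0 + timedelta(minutes=interval_minutes * k)
                             for k in range(n)])


def generate_monitor(specs: Sequence[FlySpec],
                     calendar: LightCalendar,
                     interval_minutes: float,
                     seed: int,
                     monitor_id: str = "Monitor1",
                     start_date: date | None = None,
                     end_date: date | None = None) -> tuple[MonitorData, GroundTruth]:
    """Simulate one 32-channel monitor over whole calendar dates.

    Fewer than 32 specs are padded with zero-rate flies.  The grid covers
    midnight-to-midnight over the calendar's analyzed dates (or the given
    date range), so with a non-midnight light onset the first and last
    onset-anchored experimental days are partial -- as in a real recording.
    """
    if len(specs) > N_CHANNELS:
        raise ValueError(f"at most {N_CHANNELS} fly specs per monitor")
    specs = list(specs) + [ZERO_FLY] * (N_CHANNELS - len(specs))
    idx = _time_grid(calendar, interval_minutes, start_date, end_date)
    origin = idx[0]
    hours = np.array([(t - origin).total_seconds() / 3600.0 for t in idx])
    labels = label_index(idx, calendar)
    is_ld = (labels["regime"] == LD).to_numpy()
    is_day = (labels["phase"] == "day").to_numpy()
    exp_day = labels["day"].to_numpy()
    onset = calendar.light_onset

    rng = np.random.default_rng(seed)
    count_cols = np.empty((len(idx), N_CHANNELS), dtype=np.int64)
    truth_rows = []
    zero_blocks: dict[int, list[tuple[datetime, datetime]]] = {}
    for ch, spec in enumerate(specs, start=1):
        lam = spec.rate_at(hours)
        mask = np.ones(len(idx))
        f = spec.day_active_fraction
        mask[is_ld & is_day] = 2 * f
        mask[is_ld & ~is_day] = 2 * (1 - f)
        lam = lam * mask
        if spec.death_day is not None:
            death_t = datetime.combine(spec.death_day, onset)
            lam[np.array([t >= death_t for t in idx])] = 0.0
        count_cols[:, ch - 1] = rng.poisson(lam * interval_minutes)
        # expected counts per complete experimental day, averaged over span
        day_mean = float(lam.mean() * 1440.0)
        truth_rows.append({
            "channel": ch,
            "period_h": spec.period_h if spec.amplitude > 0 else np.nan,
            "death_day": spec.death_day,
            "expected_daily_counts": day_mean,
            "baseline_rate": spec.baseline_rate,
            "amplitude": spec.amplitude,
            "waveform": spec.waveform,
        })
        blocks = []
        in_block = False
        b0 = None
        for i, v in enumerate(lam):
            if v == 0.0 and not in_block:
                in_block, b0 = True, idx[i]
            elif v > 0.0 and in_block:
                blocks.append((b0, idx[i]))
                in_block = False
        if in_block:
            blocks.append((b0, idx[-1] + timedelta(minutes=interval_minutes)))
        zero_blocks[ch] = blocks

    records = [MonitorRecord(i + 1, ts, 1, int(is_ld[i] and is_day[i]),
                             tuple(int(c) for c in count_cols[i]))
               for i, ts in enumerate(idx)]
    data = MonitorData(monitor_id, float(interval_minutes), records, [])
    truth = GroundTruth(pd.DataFrame(truth_rows).set_index("channel"),
                        zero_blocks)
    return data, truth


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectedDefect:
    kind: str          # "bad_status" | "gap"
    record_position: int
    length: int = 1


def inject_errors(data: MonitorData, seed: int,
                  n_bad_status: int = 0,
                  n_gaps: int = 0,
                  gap_len: int = 1) -> tuple[MonitorData, list[InjectedDefect]]:
    """Deterministically corrupt a monitor for validator round-trip tests.

    ``n_bad_status`` rows get status code 51; ``n_gaps`` runs of
    ``gap_len`` consecutive records are deleted.  Defect sites are chosen
    away from the series ends and from each other so that the validator
    reports exactly one issue per injected defect.
    """
    n_rec = len(data.records)
    need = n_bad_status + n_gaps * (gap_len + 2)
    if need > max(0, n_rec - 2):
        raise ValueError("too many defects for the number of records")
    rng = np.random.default_rng(seed)
    taken: set[int] = set()
    defects: list[InjectedDefect] = []

    def claim(start: int, length: int) -> bool:
        span = set(range(start - 1, start + length + 1))  # keep a buffer
        if span & taken or start < 1 or start + length >= n_rec:
            return False
        taken.update(span)
        return True

    guard = 0
    while sum(1 for d in defects if d.kind == "gap") < n_gaps:
        start = int(rng.integers(1, n_rec - gap_len))
        if claim(start, gap_len):
            defects.append(InjectedDefect("gap", start, gap_len))
        guard += 1
        if guard > 10000:
            raise RuntimeError("could not place gaps; series too short")
    while sum(1 for d in defects if d.kind == "bad_status") < n_bad_status:
        pos = int(rng.integers(1, n_rec - 1))
        if claim(pos, 1):
            defects.append(InjectedDefect("bad_status", pos))
        guard += 1
        if guard > 20000:
            raise RuntimeError("could not place bad-status rows")

    drop = {p for d in defects if d.kind == "gap"
            for p in range(d.record_position, d.record_position + d.length)}
    bad = {d.record_position for d in defects if d.kind == "bad_status"}
    records = []
    for i, rec in enumerate(data.records):
        if i in drop:
            continue
        if i in bad:
            rec = replace(rec, status_code=51)
        records.append(rec)
    corrupted = MonitorData(data.monitor_id, data.interval_minutes, records, [])
    return corrupted, sorted(defects, key=lambda d: d.record_position)
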