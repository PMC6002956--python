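"""Free-running period estimation and actogram construction.

The chi-square periodogram (Sokolove-Bushell) scores a candidate period
``p`` by folding the count series into ``K`` complete cycles of ``p`` bins
(the ragged final cycle is discarded), computing the column means
``M_h`` and the grand mean ``M`` over the folded points, and forming

    Q(p) = K * N' * sum_h (M_h - M)^2 / sum_i (x_i - M)^2,   N' = K * p,

which is approximately chi-square distributed with ``p - 1`` degrees of
freedom when no rhythm is present.  The significance line is the
upper-tail chi-square quantile with ``p - 1`` degrees of freedom; because
a periodogram scans many candidate periods at once, ``alpha`` is treated
as the family-wise level of the whole scan and the per-period quantile is
Sidak-corrected by default (``1 - (1-alpha)**(1/m)`` over ``m`` tested
periods; ``correction`` can also be ``"bonferroni"`` or ``"none"`` for
the raw per-period line).  The peak is the tested period maximizing
``Q - S`` (ties go to the shorter period), and the rhythm strength is
``Q(peak) / S(peak)``.  A fly with strength below the threshold (default
1, i.e. a peak that never clears its significance line) is classed
arrhythmic.

Periods are tested on an inclusive hour grid ``[min_h, max_h]`` at a fixed
resolution; the series is first aggregated to a bin width that makes every
tested period an integer number of bins.  Period analysis uses DD
(free-run) days; the pipeline enforces this, and a direct call on LD data
is the caller's responsibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .activity import sem
from .experiment import LightCalendar, bin_series, label_index

DEFAULT_PERIOD_RANGE_H = (18.0, 30.0)
DEFAULT_RESOLUTION_H = 0.1
DEFAULT_ALPHA = 0.05
DEFAULT_STRENGTH_THRESHOLD = 1.0
MIN_CYCLES = 3


@dataclass
class PeriodogramResult:
    fly_id: str
    periods_h: np.ndarray       # tested periods, strictly increasing
    Q: np.ndarray               # periodogram statistic per period
    S: np.ndarray               # significance line per period
    peak_period_h: float        # NaN when undefined (zero-variance series)
    rhythm_strength: float
    rhythmic: bool
    bin_minutes: float


def _as_int_minutes(hours: float, what: str) -> int:
    m = hours * 60.0
    if abs(m - round(m)) > 1e-6:
        raise ValueError(f"{what} ({hours} h) must be a whole number of minutes")
    return int(round(m))


def periodogram_bin_minutes(period_range_h: tuple[float, float],
                            resolution_h: float,
                            interval_minutes: float) -> int:
    """Largest bin width (minutes) on which every tested period is an
    integer bin count and which the acquisition interval divides."""
    lo_min = _as_int_minutes(period_range_h[0], "minimum period")
    res_min = _as_int_minutes(resolution_h, "resolution")
    g = math.gcd(lo_min, res_min)
    for cand in range(g, 0, -1):
        if g % cand:
            continue
        ratio = cand / interval_minutes
        if abs(ratio - round(ratio)) < 1e-9 and ratio >= 1 - 1e-9:
            return cand
    raise ValueError(
        f"no bin width compatible with resolution {resolution_h} h and "
        f"acquisition interval {interval_minutes} min; try a coarser "
        f"resolution such as {max(interval_minutes, g) / 60} h")


def tested_periods(period_range_h: tuple[float, float],
                   resolution_h: float) -> np.ndarray:
    lo, hi = period_range_h
    n = int(round((hi - lo) / resolution_h))
    return lo + resolution_h * np.arange(n + 1)


def chi_square_periodogram(series: pd.Series,
                           interval_minutes: float,
                           period_range_h: tuple[float, float] = DEFAULT_PERIOD_RANGE_H,
                           resolution_h: float = DEFAULT_RESOLUTION_H,
                           alpha: float = DEFAULT_ALPHA,
                           strength_threshold: float = DEFAULT_STRENGTH_THRESHOLD,
                           correction: str = "sidak",
                           fly_id: str | None = None) -> PeriodogramResult:
    """Chi-square periodogram of one fly's count series.

    The series must span at least three cycles of the longest tested
    period.  A zero-variance series yields ``rhythmic=False``, strength 0,
    and an undefined (NaN) peak.
    """
    if period_range_h[1] <= period_range_h[0] or resolution_h <= 0:
        raise ValueError("need max period > min period and resolution > 0")
    delta = periodogram_bin_minutes(period_range_h, resolution_h, interval_minutes)
    binned = bin_series(series, float(delta), interval_minutes, statistic="sum")
    x = binned.to_numpy(dtype=float)
    span_h = x.size * delta / 60.0
    if span_h < MIN_CYCLES * period_range_h[1]:
        raise ValueError(
            f"series spans {span_h:.1f} h; at least {MIN_CYCLES} cycles of the "
            f"longest tested period ({MIN_CYCLES * period_range_h[1]:.1f} h) "
            "are required")
    periods = tested_periods(period_range_h, resolution_h)
    n_tested = periods.size
    if correction == "sidak":
        alpha_eff = 1.0 - (1.0 - alpha) ** (1.0 / n_tested)
    elif correction == "bonferroni":
        alpha_eff = alpha / n_tested
    elif correction == "none":
        alpha_eff = alpha
    else:
        raise ValueError(f"correction must be sidak/bonferroni/none, got {correction!r}")
    Q = np.empty(n_tested)
    S = np.empty(n_tested)
    degenerate = False
    for i, p_h in enumerate(periods):
        p_bins = _as_int_minutes(float(p_h), "tested period") // delta
        K = x.size // p_bins
        n_used = K * p_bins
        folded = x[:n_used].reshape(K, p_bins)
        col_means = folded.mean(axis=0)
        grand = folded.mean()
        denom = np.sum((x[:n_used] - grand) ** 2)
        if denom == 0.0:
            degenerate = True
            Q[i] = 0.0
        else:
            Q[i] = K * n_used * np.sum((col_means - grand) ** 2) / denom
        S[i] = sps.chi2.ppf(1.0 - alpha_eff, p_bins - 1)
    name = fly_id or str(series.name)
    if degenerate and np.all(Q == 0.0):
        return PeriodogramResult(name, periods, Q, S, float("nan"),
                                 0.0, False, float(delta))
    excess = Q - S
    peak = int(np.argmax(excess))  # first (shortest) period on exact ties
    strength = float(Q[peak] / S[peak])
    return PeriodogramResult(name, periods, Q, S, float(periods[peak]),
                             strength, strength >= strength_threshold,
                             float(delta))


def filter_arrhythmic(results: Sequence[PeriodogramResult],
                      strength_threshold: float = DEFAULT_STRENGTH_THRESHOLD,
                      ) -> tuple[list[PeriodogramResult], list[PeriodogramResult]]:
    """Partition flies into (rhythmic, arrhythmic) by rhythm strength.

    The boundary is inclusive: strength equal to the threshold is rhythmic.
    """
    rhythmic = [r for r in results if r.rhythm_strength >= strength_threshold]
    arrhythmic = [r for r in results if r.rhythm_strength < strength_threshold]
    return rhythmic, arrhythmic


def aggregate_periodogram(results: Sequence[PeriodogramResult]) -> pd.DataFrame:
    """Pointwise mean +/- SEM of Q across flies on a shared period grid."""
    if not results:
        raise ValueError("no periodogram results to aggregate")
    grid = results[0].periods_h
    for r in results[1:]:
        if r.periods_h.shape != grid.shape or not np.allclose(r.periods_h, grid):
            raise ValueError("periodogram results use different period grids")
    qs = np.vstack([r.Q for r in results])
    return pd.DataFrame({
        "period_h": grid,
        "mean_Q": qs.mean(axis=0),
        "sem_Q": [sem(qs[:, j]) for j in range(qs.shape[1])],
        "S": results[0].S,
        "n": qs.shape[0]})


# ---------------------------------------------------------------------------
# actograms
# ---------------------------------------------------------------------------

@dataclass
class ActogramMatrix:
    """Day-by-time raster of binned counts.

    ``matrix`` rows are experimental days, columns are hours since light
    onset; double-plotted rows concatenate day d with day d+1 (the final
    row's right half is NaN where day d+1 is absent).
    """

    label: str                  # fly id, "mean", or "median"
    style: str                  # "single" | "double"
    bin_minutes: float
    matrix: pd.DataFrame


def _day_by_bin(series: pd.Series, calendar: LightCalendar,
                interval_minutes: float, bin_minutes: float) -> pd.DataFrame:
    b = bin_series(series, bin_minutes, interval_minutes, statistic="sum",
                   anchor=calendar.light_onset)
    idx = pd.DatetimeIndex(b.index)
    labels = label_index(idx, calendar)
    onset_min = calendar.light_onset.hour * 60 + calendar.light_onset.minute
    tod = (idx.hour * 60 + idx.minute - onset_min) % 1440
    frame = pd.DataFrame({"day": labels["day"].to_numpy(),
                          "bin_h": tod / 60.0,
                          "value": b.to_numpy()})
    wide = frame.pivot(index="day", columns="bin_h", values="value")
    all_bins = np.arange(int(round(1440 / bin_minutes))) * bin_minutes / 60.0
    return wide.reindex(columns=all_bins)


def build_actogram(series_map: Mapping[str, pd.Series] | pd.Series,
                   calendar: LightCalendar,
                   interval_minutes: float,
                   bin_minutes: float = 30.0,
                   style: str = "single",
                   aggregate: str | None = None) -> ActogramMatrix:
    """Actogram matrix for a single fly or a condition aggregate.

    Pass one series for an individual actogram, or a map of series with
    ``aggregate`` in ``{"mean", "median"}`` for a condition actogram; the
    aggregate is computed per (day, time bin) across flies.
    """
    if style not in ("single", "double"):
        raise ValueError(f"style must be 'single' or 'double', got {style!r}")
    if isinstance(series_map, pd.Series):
        single = _day_by_bin(series_map, calendar, interval_minutes, bin_minutes)
        label = str(series_map.name)
    else:
        if aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median' for multi-fly input")
        mats = [_day_by_bin(s, calendar, interval_minutes, bin_minutes)
                for s in series_map.values()]
        stacked = pd.concat(mats, keys=range(len(mats)))
        grouped = stacked.groupby(level=1)
        single = grouped.mean() if aggregate == "mean" else grouped.median()
        label = aggregate
    if style == "single":
        return ActogramMatrix(label, style, float(bin_minutes), single)
    days = list(single.index)
    width = single.shape[1]
    cols = np.concatenate([single.columns.to_numpy(),
                           single.columns.to_numpy() + 24.0])
    rows = []
    for i, d in enumerate(days):
        left = single.iloc[i].to_numpy()
        right = (single.iloc[i + 1].to_numpy() if i + 1 < len(days)
                 else np.full(width, np.nan))
        rows.append(np.concatenate([left, right]))
    double = pd.DataFrame(rows, index=single.index, columns=cols)
    return ActogramMatrix(label, "double", float(bin_minutes), double)
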