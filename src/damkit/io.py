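"""Reading, validating, and writing TriKinetics DAM monitor files.

DAMSystem3 "monitor" files are tab-delimited text with one reading per row
and 42 fields per row:

====== ==========================================================
field  content
====== ==========================================================
1      reading index (positive integer)
2      date, ``D Mon YY`` (e.g. ``1 Jan 17``; English month
       abbreviations; two-digit years map to 2000-2099)
3      time of day, ``HH:MM:SS``
4      status code (0 or 1 = valid reading; anything else is
       treated as a hardware-error row and dropped)
5-9    device extras (parsed, ignored, written back as zeros)
10     light-sensor flag, 0/1
11-42  beam-crossing counts for channels 1-32
====== ==========================================================

Legacy DAMSystem2 "channel" files carry one channel each as
``index  date  time  status  count`` rows; :func:`convert_channel_files`
merges up to 32 of them column-wise into one monitor file.

Validation is total: every input yields either a :class:`MonitorData`
(possibly with warnings) or a :class:`MonitorFileError` carrying the full
issue list.  Rows are never dropped silently -- each dropped row leaves a
``bad_status_code`` warning, and every repaired timestamp gap leaves a
``timestamp_gap`` warning.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_CHANNELS = 32  # channels per DAM monitor; a constant of the hardware
N_FIELDS = 42
VALID_STATUS_CODES = frozenset({0, 1})
MAX_REPAIRABLE_GAP = 6  # missing intervals; longer dropouts invalidate binning

_MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
_MONTH_NUM = {m: i + 1 for i, m in enumerate(_MONTHS)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonitorRecord:
    """One reading: timestamp, status, light sensor, and 32 channel counts."""

    reading_index: int
    timestamp: datetime
    status_code: int
    light_sensor: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} counts, got {len(self.counts)}")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ValidationIssue:
    """A problem found in one input row (row=None means the whole file)."""

    severity: str  # "warning" | "fatal"
    kind: str
    monitor_id: str
    row: int | None
    message: str

    def __str__(self) -> str:
        loc = f"{self.monitor_id}:{self.row}" if self.row is not None else self.monitor_id
        return f"[{self.severity}] {loc} {self.kind}: {self.message}"


class MonitorFileError(ValueError):
    """Raised when a monitor file has fatal integrity problems."""

    def __init__(self, monitor_id: str, issues: Sequence[ValidationIssue]):
        self.monitor_id = monitor_id
        self.issues = list(issues)
        fatal = [i for i in self.issues if i.severity == "fatal"]
        super().__init__(
            f"monitor '{monitor_id}' rejected with {len(fatal)} fatal issue(s):\n"
            + "\n".join(str(i) for i in fatal)
        )


@dataclass
class MonitorData:
    """Validated, time-ordered count matrix for one 32-channel monitor."""

    monitor_id: str
    interval_minutes: float
    records: list[MonitorRecord]
    issues: list[ValidationIssue] = field(default_factory=list)

    def counts_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by timestamp, columns = channel 1-32."""
        idx = pd.DatetimeIndex([r.timestamp for r in self.records])
        data = np.array([r.counts for r in self.records], dtype=np.int64)
        return pd.DataFrame(data, index=idx, columns=range(1, N_CHANNELS + 1))

    def channel_series(self, channel: int) -> pd.Series:
        if not 1 <= channel <= N_CHANNELS:
            raise ValueError(f"channel must be 1..{N_CHANNELS}, got {channel}")
        idx = pd.DatetimeIndex([r.timestamp for r in self.records])
        vals = np.array([r.counts[channel - 1] for r in self.records], dtype=np.int64)
        return pd.Series(vals, index=idx, name=f"{self.monitor_id}_ch{channel:02d}")

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]


def count_channels(data: MonitorData) -> int:
    """Number of per-fly count channels in a monitor file (always 32)."""
    return N_CHANNELS


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_timestamp(date_s: str, time_s: str) -> datetime:
    day_s, mon_s, year_s = date_s.strip().split()
    month = _MONTH_NUM.get(mon_s)
    if month is None:
        raise ValueError(f"unknown month abbreviation {mon_s!r}")
    year = int(year_s)
    if year < 100:
        year += 2000
    hh, mm, ss = (int(p) for p in time_s.strip().split(":"))
    return datetime(year, month, int(day_s), hh, mm, ss)


def format_timestamp(ts: datetime) -> tuple[str, str]:
    """Render a timestamp in the monitor-file date/time fields."""
    date_s = f"{ts.day} {_MONTHS[ts.month - 1]} {ts.year % 100:02d}"
    time_s = f"{ts.hour:02d}:{ts.minute:02d}:{ts.second:02d}"
    return date_s, time_s


def _parse_row(fields: list[str], monitor_id: str, row: int,
               issues: list[ValidationIssue],
               dropped_timestamps: set[datetime]) -> MonitorRecord | None:
    """Parse one 42-field row; append issues; return record or None if dropped."""
    if len(fields) != N_FIELDS:
        issues.append(ValidationIssue(
            "fatal", "wrong_column_count", monitor_id, row,
            f"expected {N_FIELDS} tab-separated fields, found {len(fields)}; "
            "check for a truncated download or a non-monitor file"))
        return None
    try:
        reading_index = int(fields[0])
        ts = _parse_timestamp(fields[1], fields[2])
        status = int(fields[3])
        light = int(fields[9])
        counts = tuple(int(c) for c in fields[10:42])
    except (ValueError, IndexError) as exc:
        issues.append(ValidationIssue(
            "fatal", "malformed_row", monitor_id, row,
            f"could not parse row: {exc}; fix the row or delete it"))
        return None
    if any(c < 0 for c in counts):
        issues.append(ValidationIssue(
            "fatal", "negative_count", monitor_id, row,
            "negative beam-crossing count; counts must be >= 0"))
        return None
    if status not in VALID_STATUS_CODES:
        issues.append(ValidationIssue(
            "warning", "bad_status_code", monitor_id, row,
            f"status code {status} indicates a hardware error; row dropped"))
        dropped_timestamps.add(ts)
        return None
    return MonitorRecord(reading_index, ts, status, light, counts)


def _check_grid(records: list[MonitorRecord], monitor_id: str,
                interval_minutes: float,
                issues: list[ValidationIssue],
                dropped_timestamps: set[datetime] | None = None) -> list[MonitorRecord]:
    """Enforce a strictly increasing, evenly spaced time grid.

    A dropout of up to MAX_REPAIRABLE_GAP intervals is repaired by inserting
    zero-count records (flagged as warnings); anything longer, a duplicate
    timestamp, or an off-grid spacing is fatal.  Holes left by rows that
    were already dropped (and warned about) for bad status codes are exempt:
    they stay holes and raise no second issue.
    """
    dropped_timestamps = dropped_timestamps or set()
    step = timedelta(minutes=interval_minutes)
    out: list[MonitorRecord] = []
    prev: MonitorRecord | None = None
    for rec in records:
        if prev is not None:
            delta = rec.timestamp - prev.timestamp
            if delta == timedelta(0):
                issues.append(ValidationIssue(
                    "fatal", "duplicate_timestamp", monitor_id, None,
                    f"duplicate timestamp {rec.timestamp}; remove the repeated row"))
                prev = rec
                continue
            n_steps, rem = divmod(delta, step)
            if rem != timedelta(0) or delta < timedelta(0):
                issues.append(ValidationIssue(
                    "fatal", "interval_mismatch", monitor_id, None,
                    f"timestamps {prev.timestamp} -> {rec.timestamp} are not "
                    f"separated by a multiple of {interval_minutes} min; "
                    "check the acquisition-interval setting"))
            elif n_steps > 1:
                missing_ts = [prev.timestamp + k * step for k in range(1, n_steps)]
                unexplained = [t for t in missing_ts if t not in dropped_timestamps]
                missing = len(unexplained)
                if missing > MAX_REPAIRABLE_GAP:
                    issues.append(ValidationIssue(
                        "fatal", "timestamp_gap", monitor_id, None,
                        f"{missing} consecutive readings missing before "
                        f"{rec.timestamp}; gaps longer than "
                        f"{MAX_REPAIRABLE_GAP} intervals cannot be repaired"))
                elif missing > 0:
                    for t in unexplained:
                        out.append(MonitorRecord(
                            prev.reading_index, t, 0, prev.light_sensor,
                            (0,) * N_CHANNELS))
                    out.sort(key=lambda r: r.timestamp)
                    issues.append(ValidationIssue(
                        "warning", "timestamp_gap", monitor_id, None,
                        f"{missing} missing reading(s) before {rec.timestamp} "
                        "filled with zero counts"))
        out.append(rec)
        prev = rec
    return out


def read_monitor_file(path: str | os.PathLike, interval_minutes: float) -> MonitorData:
    """Read and validate a DAMSystem3 monitor file.

    Parameters
    ----------
    path
        Monitor file (tab-delimited, 42 fields/row, LF or CRLF).
    interval_minutes
        Acquisition interval the file was recorded at.

    Returns
    -------
    MonitorData
        With warnings attached for dropped hardware-error rows and
        repaired single-interval gaps.

    Raises
    ------
    MonitorFileError
        On any fatal issue (wrong field count, unparseable row, negative
        count, duplicate timestamp, off-grid spacing, long gap).  The
        exception carries the complete issue list.
    """
    if interval_minutes <= 0:
        raise ValueError("interval_minutes must be positive")
    monitor_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    issues: list[ValidationIssue] = []
    records: list[MonitorRecord] = []
    dropped_ts: set[datetime] = set()
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for row, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            rec = _parse_row(line.split("\t"), monitor_id, row, issues, dropped_ts)
            if rec is not None:
                records.append(rec)
    records = _check_grid(records, monitor_id, interval_minutes, issues, dropped_ts)
    if any(i.severity == "fatal" for i in issues):
        raise MonitorFileError(monitor_id, issues)
    return MonitorData(monitor_id, float(interval_minutes), records, issues)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_monitor_file(data: MonitorData, path: str | os.PathLike) -> str:
    """Write MonitorData back to the 42-field monitor-file dialect.

    Round-trip contract: ``read_monitor_file(write_monitor_file(d))`` equals
    ``d`` in records and interval.  Device-extra fields are written as zeros.
    """
    if not data.records:
        raise ValueError("refusing to write a monitor file with no records")
    path = os.fspath(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in data.records:
            date_s, time_s = format_timestamp(rec.timestamp)
            fields = ([str(rec.reading_index), date_s, time_s, str(rec.status_code)]
                      + ["0"] * 5
                      + [str(rec.light_sensor)]
                      + [str(c) for c in rec.counts])
            fh.write("\t".join(fields) + "\n")
    return path


# ---------------------------------------------------------------------------
# DAMSystem2 conversion
# ---------------------------------------------------------------------------

def _read_channel_file(path: str | os.PathLike) -> list[tuple[datetime, int]]:
    """Read one DAM2 channel file: index, date, time, status, count."""
    out = []
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for row, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise MonitorFileError(os.path.basename(os.fspath(path)), [
                    ValidationIssue("fatal", "wrong_column_count",
                                    os.path.basename(os.fspath(path)), row,
                                    f"channel files have 5 fields, found {len(parts)}")])
            ts = _parse_timestamp(parts[1], parts[2])
            out.append((ts, int(parts[4])))
    return out


def convert_channel_files(paths: Sequence[str | os.PathLike],
                          monitor_id: str,
                          interval_minutes: float) -> MonitorData:
    """Merge 1-32 legacy DAMSystem2 per-channel files into one MonitorData.

    Channels are assigned in the order given; missing channels (fewer than
    32 files) are filled with zeros and flagged as warnings.  All files must
    share the same time grid; any disagreement is fatal.
    """
    if not 1 <= len(paths) <= N_CHANNELS:
        raise ValueError(f"need 1..{N_CHANNELS} channel files, got {len(paths)}")
    channels = [_read_channel_file(p) for p in paths]
    grid = [ts for ts, _ in channels[0]]
    issues: list[ValidationIssue] = []
    for p, ch in zip(paths, channels):
        if [ts for ts, _ in ch] != grid:
            raise MonitorFileError(monitor_id, [ValidationIssue(
                "fatal", "interval_mismatch", monitor_id, None,
                f"channel file {os.path.basename(os.fspath(p))} disagrees with "
                "the time grid of the first channel file")])
    for missing in range(len(paths) + 1, N_CHANNELS + 1):
        issues.append(ValidationIssue(
            "warning", "wrong_column_count", monitor_id, None,
            f"channel {missing} has no input file; filled with zeros"))
    records = []
    for i, ts in enumerate(grid):
        counts = tuple(ch[i][1] for ch in channels) + (0,) * (N_CHANNELS - len(channels))
        records.append(MonitorRecord(i + 1, ts, 1, 0, counts))
    grid_issues: list[ValidationIssue] = []
    records = _check_grid(records, monitor_id, interval_minutes, grid_issues)
    issues.extend(grid_issues)
    if any(i.severity == "fatal" for i in issues):
        raise MonitorFileError(monitor_id, issues)
    return MonitorData(monitor_id, float(interval_minutes), records, issues)
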