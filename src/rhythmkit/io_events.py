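"""Data model and readers/writers for event logs, actigraphy and derived series.

The common in-memory currencies are:

* :class:`EventLog` — time-stamped smartphone events (screen on/off,
  notifications, app use) for one participant.
* :class:`EpochSeries` — a uniformly sampled activity-like series
  (acti-counts, app-counts or work probabilities); missing epochs are NaN,
  never zero.
* :class:`WorkIntervalSet` — geofence- or manually-derived at-work intervals.

All timestamps are timezone-aware.  Day-level computations interpret "day"
as midnight-to-midnight in the participant's declared local timezone and
"night" as noon-to-noon (standard actigraphy convention).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from rhythmkit.errors import ParseError, ValidationError

EVENT_TYPES = ("screen_on", "screen_off", "notification", "app_use")
#: event types that carry an app label
LABELLED_EVENT_TYPES = ("notification", "app_use")

SERIES_LABELS = ("PA", "GMA", "WMA", "other")

DAY_TABLE_COLUMNS = (
    "participant_id",
    "date",
    "is_workday",
    "m10_pa",
    "m10_gma",
    "m10_wma",
    "tst_prev_min",
    "sleep_midpoint_prev_h",
    "gender_code",
    "age_years",
)


class Event(NamedTuple):
    t: datetime
    event_type: str
    app_label: str | None = None


def _check_aware(t: datetime, what: str) -> None:
    if t.tzinfo is None:
        raise ValidationError(f"{what} must be timezone-aware, got naive {t!r}")


@dataclass(frozen=True)
class EventLog:
    """Ordered smartphone event stream for one participant."""

    participant_id: str
    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        prev = None
        for i, ev in enumerate(self.events):
            _check_aware(ev.t, f"event {i} timestamp")
            if ev.event_type not in EVENT_TYPES:
                raise ValidationError(
                    f"event {i}: unknown event_type {ev.event_type!r}"
                )
            has_label = ev.app_label is not None
            needs_label = ev.event_type in LABELLED_EVENT_TYPES
            if has_label != needs_label:
                raise ValidationError(
                    f"event {i}: app_label must be present iff event_type is "
                    f"one of {LABELLED_EVENT_TYPES}, got {ev!r}"
                )
            if prev is not None and ev.t < prev:
                raise ValidationError(
                    f"events not sorted by timestamp at index {i}"
                )
            prev = ev.t

    @classmethod
    def from_events(
        cls, participant_id: str, events: Iterable[Event]
    ) -> "EventLog":
        """Build a log from possibly-unsorted events (sorts by timestamp)."""
        return cls(participant_id, tuple(sorted(events, key=lambda e: e.t)))

    def __len__(self) -> int:
        return len(self.events)

    def between(self, start: datetime, end: datetime) -> "EventLog":
        sel = tuple(e for e in self.events if start <= e.t < end)
        return EventLog(self.participant_id, sel)

    def dates(self, tz) -> list[date]:
        """Local calendar dates on which at least one event occurred."""
        return sorted({e.t.astimezone(tz).date() for e in self.events})


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled tri-axial acceleration in g-units."""

    participant_id: str
    sampling_rate_hz: float
    start: datetime
    xyz: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        _check_aware(self.start, "AccelTrace.start")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValidationError("xyz must have shape (n, 3)")
        if not np.all(np.isfinite(xyz)):
            raise ValidationError("acceleration samples must be finite")
        object.__setattr__(self, "xyz", xyz)

    @property
    def n(self) -> int:
        return self.xyz.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_rate_hz


@dataclass(frozen=True)
class EpochSeries:
    """Uniform activity-like series; missing values are NaN, never 0."""

    participant_id: str
    epoch_seconds: int
    start: datetime
    values: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        _check_aware(self.start, "EpochSeries.start")
        if int(self.epoch_seconds) != self.epoch_seconds or self.epoch_seconds <= 0:
            raise ValidationError("epoch_seconds must be a positive integer")
        if self.label not in SERIES_LABELS:
            raise ValidationError(
                f"label must be one of {SERIES_LABELS}, got {self.label!r}"
            )
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValidationError("values must be one-dimensional")
        with np.errstate(invalid="ignore"):
            if np.any(vals[np.isfinite(vals)] < 0) and self.label != "other":
                raise ValidationError("activity values must be nonnegative")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "epoch_seconds", int(self.epoch_seconds))

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=self.n * self.epoch_seconds)

    def times(self) -> list[datetime]:
        step = timedelta(seconds=self.epoch_seconds)
        return [self.start + i * step for i in range(self.n)]

    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def index_of(self, t: datetime) -> int:
        """Epoch index containing instant ``t`` (may be out of range)."""
        return math.floor((t - self.start).total_seconds() / self.epoch_seconds)

    def slice(self, start: datetime, end: datetime) -> "EpochSeries":
        i0 = max(self.index_of(start), 0)
        i1 = min(self.index_of(end - timedelta(microseconds=1)) + 1, self.n)
        i1 = max(i1, i0)
        return replace(
            self,
            start=self.start + timedelta(seconds=i0 * self.epoch_seconds),
            values=self.values[i0:i1],
        )

    def day_slice(self, day: date, tz) -> "EpochSeries":
        """Midnight-to-midnight slice of ``day`` in local timezone ``tz``."""
        start = datetime.combine(day, time(0), tzinfo=tz)
        return self.slice(start, start + timedelta(days=1))

    def with_values(self, values: np.ndarray) -> "EpochSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class WorkInterval:
    day: date
    start_time: time
    end_time: time
    source: str = "gps"

    def __post_init__(self) -> None:
        if self.source not in ("gps", "manual"):
            raise ValidationError(f"unknown interval source {self.source!r}")
        if not self.start_time < self.end_time:
            raise ValidationError(
                f"work interval on {self.day}: start must precede end"
            )

    def bounds(self, tz) -> tuple[datetime, datetime]:
        return (
            datetime.combine(self.day, self.start_time, tzinfo=tz),
            datetime.combine(self.day, self.end_time, tzinfo=tz),
        )


@dataclass(frozen=True)
class WorkIntervalSet:
    participant_id: str
    intervals: tuple[WorkInterval, ...]

    def __post_init__(self) -> None:
        by_day: dict[date, list[WorkInterval]] = {}
        for iv in self.intervals:
            by_day.setdefault(iv.day, []).append(iv)
        for day, ivs in by_day.items():
            ivs = sorted(ivs, key=lambda v: v.start_time)
            for a, b in zip(ivs, ivs[1:]):
                if b.start_time < a.end_time:
                    raise ValidationError(
                        f"overlapping work intervals on {day}"
                    )

    def work_dates(self) -> set[date]:
        return {iv.day for iv in self.intervals}

    def contains(self, t: datetime, tz) -> bool:
        local = t.astimezone(tz)
        for iv in self.intervals:
            if iv.day == local.date():
                if iv.start_time <= local.time() < iv.end_time:
                    return True
        return False

    def minute_labels(self, start: datetime, n_minutes: int, tz) -> np.ndarray:
        """Boolean at-work label for each of ``n_minutes`` minutes from ``start``."""
        labels = np.zeros(n_minutes, dtype=bool)
        for iv in self.intervals:
            lo, hi = iv.bounds(tz)
            i0 = math.ceil((lo - start).total_seconds() / 60.0)
            i1 = math.ceil((hi - start).total_seconds() / 60.0)
            i0 = max(i0, 0)
            i1 = min(i1, n_minutes)
            if i1 > i0:
                labels[i0:i1] = True
        return labels


# ---------------------------------------------------------------------------
# event log I/O


@dataclass(frozen=True)
class EventLogDialect:
    """Declared (never sniffed) on-disk layout of an event log."""

    format: str = "jsonl"  # "jsonl" or "csv"
    # CSV column names
    timestamp_col: str = "timestamp"
    type_col: str = "event_type"
    app_col: str = "app_label"
    # JSON Lines keys
    timestamp_key: str = "t"
    type_key: str = "type"
    app_key: str = "app"

    def __post_init__(self) -> None:
        if self.format not in ("jsonl", "csv"):
            raise ValidationError(f"unknown event-log format {self.format!r}")


DEFAULT_DIALECT = EventLogDialect()


def _parse_ts(raw: str, lineno: int) -> datetime:
    try:
        t = datetime.fromisoformat(raw)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed timestamp {raw!r}") from exc
    if t.tzinfo is None:
        raise ParseError(f"line {lineno}: timestamp {raw!r} lacks a UTC offset")
    return t


def read_event_log(
    path: str | Path,
    participant_id: str,
    dialect: EventLogDialect = DEFAULT_DIALECT,
) -> EventLog:
    """Read, sort and validate an event log.

    Duplicate identical rows are dropped with a single warning reporting the
    count.  Malformed timestamps raise :class:`ParseError` naming the line;
    unknown event types raise :class:`ValidationError`.
    """
    path = Path(path)
    rows: list[tuple[str, str, str | None]] = []
    lines = path.read_text().splitlines()
    if dialect.format == "jsonl":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {lineno}: invalid JSON") from exc
            rows.append(
                (
                    str(obj.get(dialect.timestamp_key, "")),
                    str(obj.get(dialect.type_key, "")),
                    obj.get(dialect.app_key),
                )
            )
    else:
        if not lines:
            return EventLog(participant_id, ())
        header = [c.strip() for c in lines[0].split(",")]
        try:
            i_t = header.index(dialect.timestamp_col)
            i_ty = header.index(dialect.type_col)
        except ValueError as exc:
            raise ParseError(f"line 1: missing required column: {exc}") from exc
        i_app = header.index(dialect.app_col) if dialect.app_col in header else None
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split(",")
            app = None
            if i_app is not None and i_app < len(parts) and parts[i_app].strip():
                app = parts[i_app].strip()
            rows.append((parts[i_t].strip(), parts[i_ty].strip(), app))

    events: list[Event] = []
    offset = 1 if dialect.format == "csv" else 0
    for i, (raw_t, raw_ty, app) in enumerate(rows):
        lineno = i + 1 + offset
        t = _parse_ts(raw_t, lineno)
        if raw_ty not in EVENT_TYPES:
            raise ValidationError(
                f"line {lineno}: unknown event_type {raw_ty!r}"
            )
        events.append(Event(t, raw_ty, app))

    uniq = sorted(set(events), key=lambda e: (e.t, e.event_type, e.app_label or ""))
    n_dup = len(events) - len(uniq)
    if n_dup:
        warnings.warn(
            f"{path.name}: dropped {n_dup} duplicate identical event rows",
            stacklevel=2,
        )
    return EventLog(participant_id, tuple(uniq))


def write_event_log(
    log: EventLog,
    path: str | Path,
    dialect: EventLogDialect = DEFAULT_DIALECT,
) -> None:
    path = Path(path)
    if dialect.format == "jsonl":
        with path.open("w") as fh:
            for ev in log.events:
                obj = {
                    dialect.timestamp_key: ev.t.isoformat(),
                    dialect.type_key: ev.event_type,
                }
                if ev.app_label is not None:
                    obj[dialect.app_key] = ev.app_label
                fh.write(json.dumps(obj) + "\n")
    else:
        with path.open("w") as fh:
            fh.write(
                f"{dialect.timestamp_col},{dialect.type_col},{dialect.app_col}\n"
            )
            for ev in log.events:
                fh.write(
                    f"{ev.t.isoformat()},{ev.event_type},{ev.app_label or ''}\n"
                )


# ---------------------------------------------------------------------------
# epoch series I/O

_SERIES_MAGIC = "# rhythmkit epoch_series v1"


def write_epoch_series(
    series: EpochSeries, path: str | Path, provenance: dict | None = None
) -> None:
    """CSV with a metadata header line; round-trips exactly through
    :func:`read_epoch_series`."""
    path = Path(path)
    meta = (
        f"{_SERIES_MAGIC} participant={series.participant_id} "
        f"epoch_seconds={series.epoch_seconds} label={series.label} "
        f"start={series.start.isoformat()}"
    )
    lines = [meta]
    if provenance:
        prov = " ".join(f"{k}={v}" for k, v in sorted(provenance.items()))
        lines.append(f"# provenance {prov}")
    lines.append("timestamp,value,missing_flag")
    step = timedelta(seconds=series.epoch_seconds)
    for i, v in enumerate(series.values):
        ts = (series.start + i * step).isoformat()
        if np.isfinite(v):
            lines.append(f"{ts},{float(v)!r},0")
        else:
            lines.append(f"{ts},,1")
    path.write_text("\n".join(lines) + "\n")


def read_epoch_series(path: str | Path) -> EpochSeries:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith(_SERIES_MAGIC):
        raise ParseError(f"{path.name}: missing epoch-series metadata header")
    meta = dict(
        kv.split("=", 1)
        for kv in lines[0][len(_SERIES_MAGIC):].strip().split(" ")
        if "=" in kv
    )
    body = [ln for ln in lines[1:] if ln and not ln.startswith("#")]
    if not body or body[0] != "timestamp,value,missing_flag":
        raise ParseError(f"{path.name}: missing column header")
    vals: list[float] = []
    for lineno, ln in enumerate(body[1:], start=2):
        _, raw_v, flag = ln.split(",")
        vals.append(np.nan if flag == "1" else float(raw_v))
    return EpochSeries(
        participant_id=meta["participant"],
        epoch_seconds=int(meta["epoch_seconds"]),
        start=datetime.fromisoformat(meta["start"]),
        values=np.asarray(vals, dtype=float),
        label=meta["label"],
    )


# ---------------------------------------------------------------------------
# work interval I/O


def read_work_intervals(path: str | Path) -> dict[str, WorkIntervalSet]:
    """CSV columns: participant_id,date,start,end,source → sets keyed by id."""
    df = pd.read_csv(path, dtype=str, comment="#")
    required = {"participant_id", "date", "start", "end"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"work interval file missing columns {required - set(df.columns)}"
        )
    out: dict[str, list[WorkInterval]] = {}
    for _, row in df.iterrows():
        iv = WorkInterval(
            day=date.fromisoformat(row["date"]),
            start_time=time.fromisoformat(row["start"]),
            end_time=time.fromisoformat(row["end"]),
            source=row.get("source", "gps") if "source" in df.columns else "gps",
        )
        out.setdefault(row["participant_id"], []).append(iv)
    return {
        pid: WorkIntervalSet(pid, tuple(ivs)) for pid, ivs in out.items()
    }


def write_work_intervals(
    sets: Sequence[WorkIntervalSet], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("participant_id,date,start,end,source\n")
        for ws in sets:
            for iv in ws.intervals:
                fh.write(
                    f"{ws.participant_id},{iv.day.isoformat()},"
                    f"{iv.start_time.isoformat()},{iv.end_time.isoformat()},"
                    f"{iv.source}\n"
                )


# ---------------------------------------------------------------------------
# actigraphy I/O


def read_accel_csv(
    path: str | Path,
    participant_id: str,
    jitter_tolerance: float = 0.25,
) -> AccelTrace:
    """Read raw acceleration CSV (timestamp,x,y,z) as a uniform trace.

    The sampling rate is the reciprocal of the median timestamp increment;
    any increment deviating from it by more than ``jitter_tolerance``
    (fractional) raises :class:`ValidationError`.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("timestamp", "x", "y", "z"):
        if col not in df.columns:
            raise ParseError(f"accel file missing column {col!r}")
    ts = pd.to_datetime(df["timestamp"], utc=False)
    if ts.dt.tz is None:
        raise ParseError("accel timestamps must carry a UTC offset")
    dt = ts.diff().dt.total_seconds().to_numpy()[1:]
    if dt.size == 0:
        raise ValidationError("accel trace needs at least 2 samples")
    step = float(np.median(dt))
    if step <= 0:
        raise ValidationError("non-increasing accel timestamps")
    if np.any(np.abs(dt - step) > jitter_tolerance * step):
        raise ValidationError("accel sampling is not uniform within tolerance")
    return AccelTrace(
        participant_id=participant_id,
        sampling_rate_hz=1.0 / step,
        start=ts.iloc[0].to_pydatetime(),
        xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def read_counts_csv(
    path: str | Path, participant_id: str, label: str = "PA"
) -> EpochSeries:
    """Read a per-minute counts CSV (timestamp,count); blanks are missing."""
    df = pd.read_csv(path, comment="#")
    for col in ("timestamp", "count"):
        if col not in df.columns:
            raise ParseError(f"counts file missing column {col!r}")
    ts = pd.to_datetime(df["timestamp"])
    start = ts.iloc[0].to_pydatetime()
    if start.tzinfo is None:
        raise ParseError("count timestamps must carry a UTC offset")
    return EpochSeries(
        participant_id=participant_id,
        epoch_seconds=60,
        start=start,
        values=pd.to_numeric(df["count"], errors="coerce").to_numpy(dtype=float),
        label=label,
    )


# ---------------------------------------------------------------------------
# day-level table


def validate_day_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-person-day table schema and invariants."""
    missing = set(DAY_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"day table missing columns {sorted(missing)}")
    if table.duplicated(subset=["participant_id", "date"]).any():
        raise ValidationError("day table has duplicate participant-date rows")
    bad_gender = ~table["gender_code"].isin([1, 2])
    if bad_gender.any():
        raise ValidationError("gender_code must be 1 (male) or 2 (female)")
    return table


def write_day_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_day_table(table).to_csv(path, index=False)


def read_day_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", parse_dates=["date"])
    df["date"] = df["date"].dt.date
    return validate_day_table(df)
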