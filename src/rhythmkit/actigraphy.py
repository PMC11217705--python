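"""Actigraphy: acceleration → acti-counts → rest/active scoring → sleep indicators.

The acti-count pipeline mirrors research-grade wrist devices: the tri-axial
acceleration is reduced to the Euclidean magnitude of its deviation from
zero (after per-axis running-median gravity removal), band-pass filtered in
the 0.5–3 Hz movement band, thresholded, integrated over 2-second segments,
and the 2-second integrals are averaged within each minute.

Rest/active scoring uses the classic Cole-Kripke one-minute-epoch rule: a
minute is scored asleep when the scaled weighted sum of its own count and
the counts of the four preceding and two following minutes falls below 1.
The published coefficients (106, 54, 58, 76, 230, 74, 67 with scale 0.001)
are the defaults; both are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from rhythmkit.errors import ConfigurationError, ValidationError
from rhythmkit.io_events import AccelTrace, EpochSeries

#: Cole et al. (1992) one-minute-epoch weights: 4 preceding minutes, the
#: current minute, 2 following minutes.
COLE_KRIPKE_WEIGHTS = (106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0)
COLE_KRIPKE_SCALE = 0.001
#: index of the "current minute" within the weight vector
COLE_KRIPKE_CENTER = 4

DEFAULT_BAND_HZ = (0.5, 3.0)
#: supra-threshold cut on the band-passed magnitude, in g-units.  The
#: device's own threshold is proprietary; this default keeps quiescent
#: (resting) signal below the cut while ordinary movement passes it.
DEFAULT_THRESHOLD_G = 0.01


@dataclass(frozen=True)
class ActiCountSeries(EpochSeries):
    """Per-minute acti-counts plus the derivation parameters."""

    threshold_used: float = DEFAULT_THRESHOLD_G
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ


@dataclass(frozen=True)
class SleepRecord:
    """Sleep indicators for one person-night (noon-to-noon window).

    ``night_date`` is the calendar date on which the night window starts
    (the evening side).  ``midpoint_h`` is expressed in continuous hours
    since midnight of ``night_date`` and therefore exceeds 24 for
    post-midnight midpoints (03:00 → 27.0).
    """

    participant_id: str
    night_date: date
    sleep_onset: datetime | None
    wake_time: datetime | None
    total_sleep_time_min: float | None
    midpoint_h: float | None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.flagged:
            return
        if self.sleep_onset is None or self.wake_time is None:
            raise ValidationError("unflagged SleepRecord must have onset/wake")
        if not self.sleep_onset < self.wake_time:
            raise ValidationError("sleep onset must precede wake time")
        span_min = (self.wake_time - self.sleep_onset).total_seconds() / 60.0
        if self.total_sleep_time_min is None or self.total_sleep_time_min > span_min + 1e-9:
            raise ValidationError("TST cannot exceed the onset→wake span")


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.zeros_like(x)
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def accel_to_acticounts(
    trace: AccelTrace,
    threshold: float = DEFAULT_THRESHOLD_G,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    filter_order: int = 4,
    median_window_s: float = 5.0,
) -> ActiCountSeries:
    """Reduce a raw acceleration trace to per-minute acti-counts.

    Stages, in order: per-axis running-median subtraction (gravity removal);
    Euclidean magnitude; zero-phase Butterworth band-pass in ``band``;
    rectification and thresholding; integration of the supra-threshold
    magnitude over 2-second segments; per-minute average of the 2-second
    integrals.  Units of the result: g·s per 2-s segment, averaged.
    """
    fs = trace.sampling_rate_hz
    if fs < 2.0 * band[1]:
        raise ConfigurationError(
            f"sampling rate {fs} Hz is below Nyquist for band top {band[1]} Hz"
        )
    if threshold < 0:
        raise ConfigurationError("threshold must be nonnegative")
    win = max(int(round(median_window_s * fs)) | 1, 1)
    xyz = trace.xyz
    dev = xyz - np.column_stack([_running_median(xyz[:, k], win) for k in range(3)])
    z = np.sqrt(np.sum(dev * dev, axis=1))
    sos = signal.butter(filter_order, band, btype="bandpass", fs=fs, output="sos")
    zf = signal.sosfiltfilt(sos, z)
    mag = np.abs(zf)
    mag = np.where(mag >= threshold, mag, 0.0)

    per_seg = max(int(round(2.0 * fs)), 1)  # samples per 2-s segment
    n_seg = mag.size // per_seg
    if n_seg == 0:
        raise ValidationError("trace shorter than one 2-second segment")
    seg_int = mag[: n_seg * per_seg].reshape(n_seg, per_seg).sum(axis=1) / fs
    seg_per_min = 30
    n_min = n_seg // seg_per_min
    if n_min == 0:
        raise ValidationError("trace shorter than one minute")
    counts = seg_int[: n_min * seg_per_min].reshape(n_min, seg_per_min).mean(axis=1)
    return ActiCountSeries(
        participant_id=trace.participant_id,
        epoch_seconds=60,
        start=trace.start,
        values=counts,
        label="PA",
        threshold_used=threshold,
        band_hz=tuple(band),
    )


def cole_kripke_score(
    counts: EpochSeries,
    weights: Sequence[float] = COLE_KRIPKE_WEIGHTS,
    scale: float = COLE_KRIPKE_SCALE,
    center: int = COLE_KRIPKE_CENTER,
) -> tuple[np.ndarray, np.ndarray]:
    """Score each minute rest (True) or active (False).

    Minute ``t`` is scored asleep iff
    ``scale * sum_k weights[k] * counts[t + k - center] < 1``.
    Window positions falling outside the series are zero-padded; minutes
    whose window is incomplete are scored anyway and flagged in the second
    returned array.  Missing counts are treated as zero within the sum.
    """
    if counts.epoch_seconds != 60:
        raise ValidationError("Cole-Kripke scoring expects 1-minute epochs")
    x = np.nan_to_num(counts.values, nan=0.0)
    n = x.size
    w = np.asarray(weights, dtype=float)
    if counts.missing_mask().all():
        raise ValidationError("cannot score an all-missing series")
    if n < w.size:
        raise ValidationError(
            f"need at least {w.size} minutes of data, got {n}"
        )
    pad_l, pad_r = center, w.size - center - 1
    xp = np.concatenate([np.zeros(pad_l), x, np.zeros(pad_r)])
    d = scale * np.convolve(xp, w[::-1], mode="valid")
    is_sleep = d < 1.0
    edge = np.zeros(n, dtype=bool)
    edge[:pad_l] = True
    if pad_r:
        edge[-pad_r:] = True
    return is_sleep, edge


def _merge_sleep_runs(
    labels: np.ndarray, tolerance_min: int
) -> list[tuple[int, int]]:
    """Maximal sleep episodes after bridging active gaps ≤ tolerance.

    Returns half-open (start, end) index pairs whose endpoints are
    sleep-labeled minutes.
    """
    idx = np.flatnonzero(labels)
    if idx.size == 0:
        return []
    episodes: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > tolerance_min:
            episodes.append((start, prev + 1))
            start = i
        prev = i
    episodes.append((start, prev + 1))
    return episodes


def sleep_indicators(
    labels: np.ndarray,
    window_start: datetime,
    participant_id: str,
    night_date: date,
    interruption_tolerance_min: int = 15,
    min_duration_min: int = 180,
    max_missing_frac: float = 0.2,
    missing: np.ndarray | None = None,
) -> SleepRecord:
    """Derive sleep onset, wake time, TST and midpoint from minute labels.

    ``labels`` covers a noon-to-noon night window starting at
    ``window_start`` (True = sleep).  The main sleep episode is the longest
    run of sleep-labeled minutes after bridging active interruptions of at
    most ``interruption_tolerance_min`` minutes; onset/wake are its
    endpoints and TST counts the sleep-labeled minutes inside them.
    Nights without an episode of ``min_duration_min`` sleep minutes — or
    with more than ``max_missing_frac`` missing labels — yield a flagged
    record with null indicators.
    """
    labels = np.asarray(labels, dtype=bool)
    if missing is not None and missing.mean() > max_missing_frac:
        return SleepRecord(participant_id, night_date, None, None, None, None, True)

    best: tuple[int, int] | None = None
    best_tst = 0
    for s, e in _merge_sleep_runs(labels, interruption_tolerance_min):
        tst = int(labels[s:e].sum())
        if tst > best_tst:
            best, best_tst = (s, e), tst
    if best is None or best_tst < min_duration_min:
        return SleepRecord(participant_id, night_date, None, None, None, None, True)

    s, e = best
    onset = window_start + timedelta(minutes=int(s))
    wake = window_start + timedelta(minutes=int(e))
    mid = onset + (wake - onset) / 2
    anchor = datetime.combine(night_date, time(0), tzinfo=window_start.tzinfo)
    midpoint_h = (mid - anchor).total_seconds() / 3600.0
    return SleepRecord(
        participant_id=participant_id,
        night_date=night_date,
        sleep_onset=onset,
        wake_time=wake,
        total_sleep_time_min=float(best_tst),
        midpoint_h=midpoint_h,
    )


def score_nights(
    counts: EpochSeries,
    tz,
    participant_id: str | None = None,
    **kwargs,
) -> list[SleepRecord]:
    """Cole-Kripke score a count series and extract one record per night.

    Nights are noon-to-noon local windows; a night is attributed to the
    calendar date of its first (evening) half.
    """
    pid = participant_id or counts.participant_id
    is_sleep, _ = cole_kripke_score(counts)
    records: list[SleepRecord] = []
    first_local = counts.start.astimezone(tz)
    night0 = first_local.date()
    if first_local.time() >= time(12):
        pass
    else:
        night0 = night0 - timedelta(days=1)
    last_local = counts.end.astimezone(tz)
    d = night0
    while datetime.combine(d, time(12), tzinfo=tz) < last_local:
        w_start = datetime.combine(d, time(12), tzinfo=tz)
        w_end = w_start + timedelta(days=1)
        i0 = counts.index_of(w_start)
        i1 = counts.index_of(w_end)
        if i0 < 0 or i1 > counts.n:
            d += timedelta(days=1)
            continue
        records.append(
            sleep_indicators(
                is_sleep[i0:i1],
                w_start,
                pid,
                d,
                missing=counts.missing_mask()[i0:i1],
                **kwargs,
            )
        )
        d += timedelta(days=1)
    return records
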