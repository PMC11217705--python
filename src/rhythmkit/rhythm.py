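"""Circadian rhythm analytics: M10 levels and Hilbert phase differences.

M10 is the mean activity over the 10 consecutive hours of highest activity
within a local day, a standard nonparametric amplitude indicator; windows
never cross midnight, so start times range 00:00–14:00.

Phase analysis band-passes each series to the 16–28 h circadian band with a
zero-phase second-order Butterworth filter, takes the analytic-signal
(Hilbert) instantaneous phase, subtracts the reference phase from the target
phase, and averages the wrapped instantaneous differences.  2π corresponds
to 24 h, so a mean difference of π/2 rad is 6 h.  Because a delayed signal
is earlier in its cycle at any instant, a delayed target gives a *negative*
phase difference; the negated quantity ``target_delay_hours`` expresses the
result as a lag with the conventional sign (positive = target delayed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np
from scipy import signal

from rhythmkit.errors import ConfigurationError, ValidationError
from rhythmkit.io_events import EpochSeries

DEFAULT_BAND_HOURS = (16.0, 28.0)
HOURS_PER_CYCLE = 24.0


@dataclass(frozen=True)
class M10Result:
    participant_id: str
    date: date
    m10_value: float | None
    window_start: time | None
    window_end: time | None
    flagged: bool = False


@dataclass(frozen=True)
class PhaseSeries:
    participant_id: str
    epoch_seconds: int
    start: datetime
    filtered: np.ndarray
    phase: np.ndarray  # radians in (-pi, pi]
    band_hours: tuple[float, float] = DEFAULT_BAND_HOURS

    def __post_init__(self) -> None:
        if self.filtered.size != self.phase.size:
            raise ValidationError("filtered and phase must have equal length")


@dataclass(frozen=True)
class PhaseDifference:
    """Averaged instantaneous phase difference, target minus reference.

    ``mean_diff_hours`` is the plain unit conversion of ``mean_diff_rad``
    (24 h = 2π), wrapped to (−12, 12].  Because a delayed signal is earlier
    in its cycle at any instant, a *delayed* target has a *negative* mean
    phase difference; ``target_delay_hours = −mean_diff_hours`` restates
    the result as a lag (positive = target delayed relative to reference),
    which is how circadian phase relations are usually quoted.
    """

    mean_diff_rad: float
    mean_diff_hours: float
    target_delay_hours: float
    n_samples: int
    circular_dispersion: float


def wrap_phase(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap radians to (-pi, pi]."""
    return -((-np.asarray(x) + np.pi) % (2.0 * np.pi) - np.pi)


def m10(
    series: EpochSeries,
    day: date,
    tz=None,
    window_hours: float = 10.0,
    min_coverage: float = 0.8,
) -> M10Result:
    """Mean activity over the best 10-hour window of a local day.

    The window slides at the series' epoch resolution over start times
    00:00–14:00; ties break to the earliest start.  Days with less than
    ``min_coverage`` nonmissing epochs yield a flagged null result.
    Window means ignore missing epochs.
    """
    tz = tz or series.start.tzinfo
    day_series = series.day_slice(day, tz)
    per_day = int(86400 // series.epoch_seconds)
    v = day_series.values
    if v.size < per_day:
        pad = np.full(per_day - v.size, np.nan)
        v = np.concatenate([v, pad])
    v = v[:per_day]
    finite = np.isfinite(v)
    if finite.mean() < min_coverage:
        return M10Result(series.participant_id, day, None, None, None, True)

    w = int(round(window_hours * 3600 / series.epoch_seconds))
    vals = np.where(finite, v, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(int))])
    n_starts = per_day - w + 1  # last start = 24h - 10h = 14:00
    sums = csum[w : w + n_starts] - csum[:n_starts]
    cnts = ccnt[w : w + n_starts] - ccnt[:n_starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts > 0, sums / cnts, -np.inf)
    best = int(np.argmax(means))  # argmax takes the earliest maximum
    if not np.isfinite(means[best]):
        return M10Result(series.participant_id, day, None, None, None, True)
    start_s = best * series.epoch_seconds
    end_s = start_s + w * series.epoch_seconds
    to_time = lambda s: (datetime.min + timedelta(seconds=s % 86400)).time()
    return M10Result(
        participant_id=series.participant_id,
        date=day,
        m10_value=float(means[best]),
        window_start=to_time(start_s),
        window_end=to_time(end_s),
    )


def circadian_filter(
    series: EpochSeries,
    band_hours: tuple[float, float] = DEFAULT_BAND_HOURS,
    order: int = 2,
) -> EpochSeries:
    """Zero-phase Butterworth band-pass to the circadian band.

    ``band_hours`` gives the period range (default 16–28 h); ``order`` is
    the prototype filter order before the forward-backward (zero-phase)
    application, which squares the magnitude response.  Requires at least
    3 days of data and no missing values (impute first).
    """
    fs = 1.0 / series.epoch_seconds  # Hz
    if series.n * series.epoch_seconds < 3 * 86400:
        raise ValidationError("phase analysis needs at least 3 days of data")
    if series.missing_mask().any():
        raise ValidationError(
            "circadian_filter requires a complete series; impute missing first"
        )
    lo_hz = 1.0 / (band_hours[1] * 3600.0)
    hi_hz = 1.0 / (band_hours[0] * 3600.0)
    if hi_hz >= fs / 2:
        raise ConfigurationError("epoch length too coarse for the band")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    x = series.values - np.nanmean(series.values)
    y = signal.sosfiltfilt(sos, x)
    return EpochSeries(
        participant_id=series.participant_id,
        epoch_seconds=series.epoch_seconds,
        start=series.start,
        values=y - y.mean(),
        label="other",
    )


def hilbert_phase(
    filtered: EpochSeries, band_hours: tuple[float, float] = DEFAULT_BAND_HOURS
) -> PhaseSeries:
    """Instantaneous phase of a zero-mean band-limited series.

    The phase is the argument of the analytic signal x + i·H[x]; for
    cos(2πt/T) it is 0 at each cycle peak and advances by 2π per period.
    """
    x = np.asarray(filtered.values, dtype=float)
    if not np.any(x != 0.0):
        raise ValidationError("phase is undefined for an all-zero signal")
    analytic = signal.hilbert(x)
    return PhaseSeries(
        participant_id=filtered.participant_id,
        epoch_seconds=filtered.epoch_seconds,
        start=filtered.start,
        filtered=x,
        phase=np.angle(analytic),
        band_hours=tuple(band_hours),
    )


def phase_difference(
    target: PhaseSeries,
    reference: PhaseSeries,
    trim_hours: float = 12.0,
    method: str = "circular",
) -> PhaseDifference:
    """Average instantaneous phase difference, target minus reference.

    Δφ(t) = φ_target(t) − φ_reference(t), wrapped to (−π, π].  The default
    averaging is circular (argument of the mean resultant vector), which is
    immune to wrap-around; ``method="arithmetic"`` averages the wrapped
    differences directly.  The first and last ``trim_hours`` are excluded
    to avoid Hilbert edge effects.  ``mean_diff_hours`` is radians × 24/2π
    wrapped to (−12, 12]; ``target_delay_hours`` is its negation, so that a
    positive value means the target is delayed relative to the reference.
    """
    if target.phase.size != reference.phase.size:
        raise ValidationError("phase series must have equal length")
    if target.epoch_seconds != reference.epoch_seconds:
        raise ValidationError("phase series must share the epoch length")
    if method not in ("circular", "arithmetic"):
        raise ConfigurationError(f"unknown averaging method {method!r}")
    k = int(round(trim_hours * 3600 / target.epoch_seconds))
    n = target.phase.size
    if 2 * k >= n:
        raise ValidationError("series too short for the requested edge trim")
    sl = slice(k, n - k) if k else slice(None)
    dphi = wrap_phase(target.phase[sl] - reference.phase[sl])
    z = np.exp(1j * dphi).mean()
    if method == "circular":
        mean_rad = float(np.angle(z))
    else:
        mean_rad = float(wrap_phase(dphi.mean()))
    hours = mean_rad * HOURS_PER_CYCLE / (2.0 * np.pi)
    if hours <= -HOURS_PER_CYCLE / 2:
        hours += HOURS_PER_CYCLE
    delay = -hours
    if delay <= -HOURS_PER_CYCLE / 2:
        delay += HOURS_PER_CYCLE
    return PhaseDifference(
        mean_diff_rad=mean_rad,
        mean_diff_hours=hours,
        target_delay_hours=delay,
        n_samples=int(dphi.size),
        circular_dispersion=float(1.0 - np.abs(z)),
    )


def impute_missing(series: EpochSeries, seed: int | np.random.Generator) -> EpochSeries:
    """Replace each missing epoch by a draw (with replacement) from the
    series' nonmissing values; deterministic under ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = series.values.copy()
    miss = ~np.isfinite(v)
    donors = v[~miss]
    if donors.size == 0:
        raise ValidationError("cannot impute an all-missing series")
    if miss.any():
        v[miss] = rng.choice(donors, size=int(miss.sum()), replace=True)
    return series.with_values(v)


def to_epoch(series: EpochSeries, epoch_seconds: int) -> EpochSeries:
    """Mean-aggregate to a coarser epoch (must divide evenly).

    A coarse epoch is missing iff all constituent fine epochs are missing.
    """
    if epoch_seconds == series.epoch_seconds:
        return series
    if epoch_seconds % series.epoch_seconds:
        raise ConfigurationError("target epoch must be a multiple of the source")
    k = epoch_seconds // series.epoch_seconds
    n = (series.n // k) * k
    blocks = series.values[:n].reshape(-1, k)
    with np.errstate(invalid="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)
            out = np.nanmean(blocks, axis=1)
    return EpochSeries(
        participant_id=series.participant_id,
        epoch_seconds=epoch_seconds,
        start=series.start,
        values=out,
        label=series.label,
    )
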