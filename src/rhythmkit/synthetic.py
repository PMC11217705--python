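"""Synthetic cohort generator with known ground truth.

Emulates the three observed streams — per-minute wrist acti-counts,
smartphone event logs, and geofence-derived work intervals — for a cohort
shaped like a small occupational field study: 24 participants observed for
about 19 days each (~457 person-days), with weekday office schedules,
night-to-night variation in sleep timing, work/leisure/sleep contrasts in
smartphone interaction rates, and ~5% of person-days with the device off
entirely.  Every latent quantity (true sleep windows, per-minute work
labels, injected sleep→activity effect sizes, per-participant intercepts)
is returned alongside the data so each pipeline stage can be scored
against a recoverable truth.

Events are drawn from piecewise-homogeneous Poisson processes whose rates
switch at work/leisure/sleep boundaries; the screen state follows a
two-state Markov chain at minute resolution so that screen_on/screen_off
events are always consistently ordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from rhythmkit.errors import ValidationError
from rhythmkit.io_events import (
    EpochSeries,
    Event,
    EventLog,
    WorkInterval,
    WorkIntervalSet,
)

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class RegimeRates:
    """Per-minute event rates (Poisson) and screen-state switch probabilities."""

    app_use: float
    notification: float
    p_screen_on: float  # P(off → on) per minute
    p_screen_off: float  # P(on → off) per minute

    def __post_init__(self) -> None:
        for v in (self.app_use, self.notification, self.p_screen_on, self.p_screen_off):
            if v < 0:
                raise ValidationError("rates must be nonnegative")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for the synthetic cohort."""

    n_participants: int = 24
    n_days: int = 19
    start_date: date = date(2023, 1, 2)  # a Monday
    timezone: str = "Asia/Taipei"
    # work schedule
    work_start_h: float = 9.0
    work_end_h: float = 17.5
    workday_pattern: tuple[int, ...] = (0, 1, 2, 3, 4)  # Mon–Fri
    schedule_jitter_min: float = 10.0
    # sleep model
    sleep_onset_mean_h: float = 23.5
    sleep_onset_sd_h: float = 0.5
    wake_mean_h: float = 7.0
    wake_sd_h: float = 0.5
    # interaction-rate model ("strong contrast" between work and leisure)
    work_rates: RegimeRates = RegimeRates(1.0, 0.30, 0.30, 0.10)
    leisure_rates: RegimeRates = RegimeRates(0.30, 0.20, 0.12, 0.25)
    sleep_rates: RegimeRates = RegimeRates(0.005, 0.03, 0.003, 0.8)
    n_apps: int = 12
    # physical-activity model (counts in arbitrary device units)
    pa_base_amp: float = 70.0
    pa_noise_sd: float = 12.0
    pa_peak_h: float = 14.0
    sleep_count_sd: float = 0.2
    # circadian phase lags of the mental-activity rates relative to PA
    lag_gma_min: float = 73.0
    lag_wma_min: float = -65.0
    # association-model effect sizes (per 1-SD sleep indicator, on the
    # multiplicative PA amplitude scale)
    beta_midpoint: float = -0.3
    beta_tst: float = 0.0
    random_intercept_sd: float = 0.5
    residual_sd: float = 1.0
    effect_scale: float = 0.1
    # device-off days
    empty_day_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValidationError("cohort must have >= 1 participant and day")
        if not set(self.workday_pattern) <= set(range(7)):
            raise ValidationError("workday_pattern must be days of week 0–6")
        if not 0 <= self.empty_day_rate < 1:
            raise ValidationError("empty_day_rate must be in [0, 1)")

    @property
    def tz(self) -> ZoneInfo:
        return ZoneInfo(self.timezone)


@dataclass
class ParticipantTruth:
    participant_id: str
    sleep_windows: list[tuple[datetime, datetime]]
    work_labels: np.ndarray  # per-minute bool over the span
    sleep_minutes: np.ndarray  # per-minute bool over the span
    excluded_days: list[date]
    random_intercept: float
    z_midpoint: np.ndarray  # per night, standardized midpoint deviation
    z_tst: np.ndarray
    daily_amp: np.ndarray  # per day, PA amplitude actually used
    beta_midpoint: float
    beta_tst: float


@dataclass
class ParticipantBundle:
    participant_id: str
    acti_counts: EpochSeries
    event_log: EventLog
    work_intervals: WorkIntervalSet
    truth: ParticipantTruth


@dataclass
class CohortBundle:
    config: ScenarioConfig
    participants: list[ParticipantBundle]
    demographics: pd.DataFrame  # participant_id, gender_code, age_years


def _profile(hour_of_day: np.ndarray, peak_h: float) -> np.ndarray:
    """Raised-cosine diurnal profile in [0, 1], peaking at ``peak_h``."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (hour_of_day - peak_h) / 24.0))


def generate_participant(
    cfg: ScenarioConfig, index: int
) -> ParticipantBundle:
    """One participant's acti-counts, event log, work intervals and truth."""
    rng = np.random.default_rng([cfg.seed, index])
    tz = cfg.tz
    pid = f"P{index:02d}"
    span_start = datetime.combine(cfg.start_date, time(0), tzinfo=tz)
    n_min = cfg.n_days * MINUTES_PER_DAY
    minutes_h = (np.arange(n_min) % MINUTES_PER_DAY) / 60.0

    # --- sleep windows (night d: onset evening of day d, wake morning d+1)
    sleep = np.zeros(n_min, dtype=bool)
    windows: list[tuple[datetime, datetime]] = []
    z_mid = np.zeros(cfg.n_days)
    z_tst = np.zeros(cfg.n_days)
    for d in range(cfg.n_days):
        onset_h = rng.normal(cfg.sleep_onset_mean_h, cfg.sleep_onset_sd_h)
        wake_h = rng.normal(cfg.wake_mean_h, cfg.wake_sd_h)
        onset = span_start + timedelta(days=d, hours=float(onset_h))
        wake = span_start + timedelta(days=d + 1, hours=float(wake_h))
        windows.append((onset, wake))
        i0 = max(int((onset - span_start).total_seconds() // 60), 0)
        i1 = min(int((wake - span_start).total_seconds() // 60), n_min)
        sleep[i0:i1] = True
        mid_h = (onset_h + 24.0 + wake_h) / 2.0
        mid_mean = (cfg.sleep_onset_mean_h + 24.0 + cfg.wake_mean_h) / 2.0
        mid_sd = 0.5 * math.hypot(cfg.sleep_onset_sd_h, cfg.wake_sd_h)
        z_mid[d] = (mid_h - mid_mean) / mid_sd
        tst_h = 24.0 + wake_h - onset_h
        tst_sd = math.hypot(cfg.sleep_onset_sd_h, cfg.wake_sd_h)
        z_tst[d] = (tst_h - (24.0 + cfg.wake_mean_h - cfg.sleep_onset_mean_h)) / tst_sd

    # --- work schedule
    intervals: list[WorkInterval] = []
    for d in range(cfg.n_days):
        day = cfg.start_date + timedelta(days=d)
        if day.weekday() not in cfg.workday_pattern:
            continue
        j1 = rng.normal(0.0, cfg.schedule_jitter_min) / 60.0
        j2 = rng.normal(0.0, cfg.schedule_jitter_min) / 60.0
        s_h = min(max(cfg.work_start_h + j1, 0.0), 23.5)
        e_h = min(max(cfg.work_end_h + j2, s_h + 1.0), 23.99)
        to_time = lambda h: time(int(h), int((h * 60) % 60), int((h * 3600) % 60))
        intervals.append(WorkInterval(day, to_time(s_h), to_time(e_h), "gps"))
    work_set = WorkIntervalSet(pid, tuple(intervals))
    work_labels = work_set.minute_labels(span_start, n_min, tz)
    work_labels = work_labels & ~sleep

    # --- PA counts with injected sleep→activity effects
    u_i = rng.normal(0.0, cfg.random_intercept_sd)
    daily_amp = np.zeros(cfg.n_days)
    counts = np.empty(n_min)
    prof = _profile(minutes_h, cfg.pa_peak_h)
    for d in range(cfg.n_days):
        # day d is modulated by the *previous* night's sleep (night d-1)
        zm = z_mid[d - 1] if d > 0 else 0.0
        zt = z_tst[d - 1] if d > 0 else 0.0
        eps = rng.normal(0.0, cfg.residual_sd)
        mod = u_i + cfg.beta_midpoint * zm + cfg.beta_tst * zt + eps
        amp = cfg.pa_base_amp * math.exp(cfg.effect_scale * mod)
        daily_amp[d] = amp
        sl = slice(d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY)
        base = amp * (0.3 + 0.7 * prof[sl])
        counts[sl] = base + rng.normal(0.0, cfg.pa_noise_sd, MINUTES_PER_DAY)
    counts = np.clip(counts, 0.0, None)
    counts[sleep] = np.abs(rng.normal(0.0, cfg.sleep_count_sd, int(sleep.sum())))

    # --- event regimes and rates
    regime = np.where(sleep, 0, np.where(work_labels, 2, 1))  # 0 sleep,1 leisure,2 work
    rates = {0: cfg.sleep_rates, 1: cfg.leisure_rates, 2: cfg.work_rates}
    gma_prof = 0.6 + 0.8 * _profile(
        minutes_h - cfg.lag_gma_min / 60.0, cfg.pa_peak_h
    )
    app_rate = np.choose(regime, [r.app_use for r in (rates[0], rates[1], rates[2])])
    app_rate = app_rate * np.where(regime == 1, gma_prof, 1.0)
    notif_rate = np.choose(
        regime, [r.notification for r in (rates[0], rates[1], rates[2])]
    )

    events: list[Event] = []
    app_n = rng.poisson(app_rate)
    notif_n = rng.poisson(notif_rate)
    apps = [f"app{k:02d}" for k in range(cfg.n_apps)]
    for t in np.flatnonzero(app_n):
        for s in sorted(rng.uniform(0.0, 60.0, app_n[t])):
            events.append(
                Event(
                    span_start + timedelta(minutes=int(t), seconds=float(s)),
                    "app_use",
                    apps[int(rng.integers(cfg.n_apps))],
                )
            )
    for t in np.flatnonzero(notif_n):
        for s in sorted(rng.uniform(0.0, 60.0, notif_n[t])):
            events.append(
                Event(
                    span_start + timedelta(minutes=int(t), seconds=float(s)),
                    "notification",
                    apps[int(rng.integers(cfg.n_apps))],
                )
            )
    # two-state screen chain
    on = False
    switch_u = rng.uniform(size=n_min)
    for t in range(n_min):
        r = rates[int(regime[t])]
        if not on and switch_u[t] < r.p_screen_on:
            on = True
            events.append(
                Event(span_start + timedelta(minutes=t, seconds=1.0), "screen_on", None)
            )
        elif on and switch_u[t] < r.p_screen_off:
            on = False
            events.append(
                Event(span_start + timedelta(minutes=t, seconds=2.0), "screen_off", None)
            )

    # --- device-off (empty) days
    excluded: list[date] = []
    if cfg.empty_day_rate > 0:
        off = rng.uniform(size=cfg.n_days) < cfg.empty_day_rate
        for d in np.flatnonzero(off):
            excluded.append(cfg.start_date + timedelta(days=int(d)))
        if excluded:
            drop = set(excluded)
            events = [
                e for e in events if e.t.astimezone(tz).date() not in drop
            ]

    log = EventLog.from_events(pid, events)
    acti = EpochSeries(
        participant_id=pid,
        epoch_seconds=60,
        start=span_start,
        values=counts,
        label="PA",
    )
    truth = ParticipantTruth(
        participant_id=pid,
        sleep_windows=windows,
        work_labels=work_labels,
        sleep_minutes=sleep,
        excluded_days=excluded,
        random_intercept=u_i,
        z_midpoint=z_mid,
        z_tst=z_tst,
        daily_amp=daily_amp,
        beta_midpoint=cfg.beta_midpoint,
        beta_tst=cfg.beta_tst,
    )
    return ParticipantBundle(pid, acti, log, work_set, truth)


def generate_cohort(cfg: ScenarioConfig) -> CohortBundle:
    """Deterministic (seeded) cohort of participants plus demographics."""
    rng = np.random.default_rng([cfg.seed, 10**6])
    participants = [
        generate_participant(cfg, i) for i in range(cfg.n_participants)
    ]
    # demographic mix modeled on a hospital-staff cohort: mostly female,
    # ages ~ N(39.7, 8.3)
    gender = np.where(rng.uniform(size=cfg.n_participants) < 21 / 24, 2, 1)
    age = np.clip(rng.normal(39.7, 8.3, cfg.n_participants), 22.0, 65.0)
    demo = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "gender_code": gender.astype(int),
            "age_years": np.round(age, 1),
        }
    )
    return CohortBundle(cfg, participants, demo)


def generate_lagged_pair(
    lag_minutes: float,
    n_days: int = 7,
    epoch_seconds: int = 300,
    noise_sd: float = 0.3,
    seed: int = 0,
    timezone: str = "Asia/Taipei",
) -> tuple[EpochSeries, EpochSeries]:
    """A (target, reference) pair of noisy 24-h sinusoids with a known lag.

    Positive ``lag_minutes`` delays the target relative to the reference.
    """
    rng = np.random.default_rng(seed)
    tz = ZoneInfo(timezone)
    start = datetime(2023, 1, 2, tzinfo=tz)
    n = n_days * 86400 // epoch_seconds
    t_h = np.arange(n) * epoch_seconds / 3600.0
    ref = np.cos(2.0 * np.pi * t_h / 24.0) + rng.normal(0.0, noise_sd, n)
    tgt = np.cos(2.0 * np.pi * (t_h - lag_minutes / 60.0) / 24.0) + rng.normal(
        0.0, noise_sd, n
    )
    mk = lambda pid, v: EpochSeries(
        participant_id=pid,
        epoch_seconds=epoch_seconds,
        start=start,
        values=v,
        label="other",
    )
    return mk("target", tgt), mk("reference", ref)


def simulate_day_table(
    n_participants: int = 24,
    n_days: int = 19,
    beta_midpoint: float = -0.3,
    beta_tst: float = 0.0,
    beta_gender: float = 0.0,
    beta_age: float = 0.0,
    random_intercept_sd: float = 0.5,
    residual_sd: float = 1.0,
    midpoint_sd_h: float = 1.0,
    tst_sd_min: float = 60.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Day-level table drawn directly from the two-level generative model.

    The outcome (written to ``m10_pa``/``m10_gma``/``m10_wma`` alike) is

        y = β_mid·(mid − 27)/sd_h·sd_h⁻¹ … in per-unit terms:
        y = β_mid·z_mid + β_tst·z_tst + β_g·gender + β_a·age + u_i + ε

    with midpoint = 27 + midpoint_sd_h·z_mid hours and
    TST = 416 + tst_sd_min·z_tst minutes, so the *raw* fixed effects are
    β_mid/midpoint_sd_h per hour and β_tst/tst_sd_min per minute.
    Returns (table, truth) where truth holds the raw-scale coefficients.
    """
    rng = np.random.default_rng(seed)
    rows = []
    start = date(2023, 1, 2)
    for i in range(n_participants):
        pid = f"P{i:02d}"
        u = rng.normal(0.0, random_intercept_sd)
        gender = int(rng.integers(1, 3))
        age = float(np.round(rng.normal(39.7, 8.3), 1))
        z_mid = rng.normal(0.0, 1.0, n_days)
        z_tst = rng.normal(0.0, 1.0, n_days)
        eps = rng.normal(0.0, residual_sd, n_days)
        y = (
            beta_midpoint * z_mid
            + beta_tst * z_tst
            + beta_gender * gender
            + beta_age * age
            + u
            + eps
        )
        for d in range(n_days):
            rows.append(
                {
                    "participant_id": pid,
                    "date": start + timedelta(days=d),
                    "is_workday": (start + timedelta(days=d)).weekday() < 5,
                    "m10_pa": y[d],
                    "m10_gma": y[d],
                    "m10_wma": y[d],
                    "tst_prev_min": 416.0 + tst_sd_min * z_tst[d],
                    "sleep_midpoint_prev_h": 27.0 + midpoint_sd_h * z_mid[d],
                    "gender_code": gender,
                    "age_years": age,
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "beta_midpoint_per_h": beta_midpoint / midpoint_sd_h,
        "beta_tst_per_min": beta_tst / tst_sd_min,
        "random_intercept_var": random_intercept_sd**2,
        "residual_var": residual_sd**2,
    }
    return table, truth
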