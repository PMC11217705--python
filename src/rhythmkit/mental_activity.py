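"""General and working mental activity from smartphone event logs.

GMA (general mental activity) counts the apps used per minute and sums the
minute counts into 5-minute nonoverlapping epochs (288 per day), producing an
activity-like series comparable to actigraphy counts.

WMA (working mental activity) is a per-minute probability of being in work
mode, produced in two stages, each trained per participant on a
chronological 80:20 person-day split:

1. gradient-boosted trees map windowed interaction features (event counts,
   distinct apps, recency, screen-on fraction) to a minute-level work
   probability, supervised by geofence-derived work intervals;
2. the probability sequence is re-encoded as a run-length grayscale (for
   each minute, the length of the maximal contiguous run whose values stay
   within a threshold θ of that minute's value, normalized by the day
   length), tiled into 30×30 images of 30-minute rows, and a small 2-D
   convolutional network classifies each image at work / off work.  At
   prediction time the classifier's interval probabilities are fed back
   into the look-back portion of subsequent images.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from xgboost import XGBClassifier

from rhythmkit.cnn import SmallCnn
from rhythmkit.errors import ConfigurationError, ValidationError
from rhythmkit.io_events import EpochSeries, EventLog, WorkIntervalSet

MINUTES_PER_DAY = 1440
EPOCHS_PER_DAY_5MIN = 288

FEATURE_COLUMNS = (
    "n_screen_on",
    "n_screen_off",
    "n_notification",
    "n_app_use",
    "n_distinct_apps",
    "minutes_since_last_event",
    "screen_on_fraction",
)


@dataclass(frozen=True)
class WorkProbSeries(EpochSeries):
    """Minute-resolution work-mode probabilities in [0, 1]."""

    stage: str = "stage1"  # "stage1" or "final"

    def __post_init__(self) -> None:
        super().__post_init__()
        v = self.values
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("work probabilities must lie in [0, 1]")
        if self.stage not in ("stage1", "final"):
            raise ValidationError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class WmaConfig:
    """Tunable parameters of the two-stage work-mode model."""

    window_minutes: int = 10
    runlength_threshold: float = 0.1
    image_side: int = 30
    image_unit_minutes: int = 30
    image_stride_intervals: int = 1
    cnn_arch: str = "small_cnn"
    split_ratio: float = 0.8
    #: if True, each emitted interval probability is written back (as its
    #: hard decision) over the working series so later images see it in
    #: their look-back; if False (default) the look-back is always the
    #: stage-1 probabilities.  See generate_wma.
    feedback: bool = False
    seed: int = 0
    # stage-1 boosted-tree hyperparameters
    xgb_estimators: int = 100
    xgb_max_depth: int = 4
    xgb_learning_rate: float = 0.2
    # stage-2 training hyperparameters
    cnn_epochs: int = 15
    cnn_batch_size: int = 64
    cnn_learning_rate: float = 2e-3

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValidationError("split_ratio must lie strictly in (0, 1)")
        if self.runlength_threshold <= 0:
            raise ValidationError("runlength_threshold must be positive")
        if self.image_unit_minutes != self.image_side:
            raise ValidationError(
                "square images require image_unit_minutes == image_side"
            )
        if self.cnn_arch != "small_cnn":
            raise ConfigurationError(
                f"unsupported cnn_arch {self.cnn_arch!r}; available: small_cnn"
            )
        if self.window_minutes < 1:
            raise ValidationError("window_minutes must be >= 1")

    @property
    def image_minutes(self) -> int:
        return self.image_side * self.image_unit_minutes


# ---------------------------------------------------------------------------
# GMA


def _minute_index(events, start: datetime) -> np.ndarray:
    return np.array(
        [math.floor((e.t - start).total_seconds() / 60.0) for e in events],
        dtype=int,
    )


def use_counts(log: EventLog, day: date, tz=None) -> EpochSeries:
    """Apps used per minute over one local day.

    Minute ``t`` holds the count of ``app_use`` events in [t, t+1 min).
    A day on which the log records no events at all (device off) is
    returned all-missing, never all-zero.
    """
    tz = tz or (log.events[0].t.tzinfo if log.events else None)
    if tz is None:
        raise ValidationError("empty log needs an explicit timezone")
    start = datetime.combine(day, time(0), tzinfo=tz)
    end = start + timedelta(days=1)
    day_log = log.between(start, end)
    if len(day_log) == 0:
        vals = np.full(MINUTES_PER_DAY, np.nan)
    else:
        uses = [e for e in day_log.events if e.event_type == "app_use"]
        idx = _minute_index(uses, start)
        vals = np.bincount(idx, minlength=MINUTES_PER_DAY).astype(float)
    return EpochSeries(
        participant_id=log.participant_id,
        epoch_seconds=60,
        start=start,
        values=vals,
        label="GMA",
    )


def app_counts(minutes: EpochSeries) -> EpochSeries:
    """Sum minute-level use counts into 5-minute nonoverlapping epochs.

    A full day yields exactly 288 epochs.  An epoch is missing iff all of
    its 5 constituent minutes are missing; otherwise it is the sum of the
    nonmissing minutes.
    """
    if minutes.epoch_seconds != 60:
        raise ValidationError("app_counts expects a 1-minute series")
    offset = (minutes.start.minute % 5) * 60 + minutes.start.second
    if offset or minutes.start.microsecond:
        raise ValidationError("minute series must start on a 5-minute boundary")
    n = (minutes.n // 5) * 5
    blocks = minutes.values[:n].reshape(-1, 5)
    finite = np.isfinite(blocks)
    sums = np.where(finite, blocks, 0.0).sum(axis=1)
    out = np.where(finite.any(axis=1), sums, np.nan)
    return EpochSeries(
        participant_id=minutes.participant_id,
        epoch_seconds=300,
        start=minutes.start,
        values=out,
        label="GMA",
    )


# ---------------------------------------------------------------------------
# WMA stage 1: windowed interaction features → boosted-tree probabilities


def _span(log: EventLog, tz) -> tuple[datetime, int]:
    dates = log.dates(tz)
    if not dates:
        raise ValidationError("event log is empty: zero usable minutes")
    start = datetime.combine(dates[0], time(0), tzinfo=tz)
    n_days = (dates[-1] - dates[0]).days + 1
    return start, n_days * MINUTES_PER_DAY


def stage1_features(
    log: EventLog,
    work: WorkIntervalSet,
    cfg: WmaConfig,
    tz=None,
) -> pd.DataFrame:
    """One labelled feature row per minute of the log's observation span.

    Features summarize the centered ``window_minutes`` window around each
    minute; windows with no events yield all-zero features (recency capped
    at one day), never missing.  ``label`` is 1 iff the minute lies inside
    a work interval.
    """
    tz = tz or (log.events[0].t.tzinfo if log.events else None)
    if tz is None or len(log) == 0:
        raise ValidationError("zero usable minutes in event log")
    start, n_min = _span(log, tz)

    idx_all = _minute_index(log.events, start)
    types = np.array([e.event_type for e in log.events])
    counts = {
        ty: np.bincount(idx_all[types == ty], minlength=n_min).astype(float)
        for ty in ("screen_on", "screen_off", "notification", "app_use")
    }

    half = cfg.window_minutes // 2
    lo_off, hi_off = -half, cfg.window_minutes - half  # window [t+lo, t+hi)

    def window_sum(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(x)])
        lo = np.clip(np.arange(n_min) + lo_off, 0, n_min)
        hi = np.clip(np.arange(n_min) + hi_off, 0, n_min)
        return c[hi] - c[lo]

    feats = {
        "n_screen_on": window_sum(counts["screen_on"]),
        "n_screen_off": window_sum(counts["screen_off"]),
        "n_notification": window_sum(counts["notification"]),
        "n_app_use": window_sum(counts["app_use"]),
    }

    # distinct app labels in each window: sliding multiset over app_use events
    app_events = [
        (i, e.app_label)
        for i, e in zip(idx_all, log.events)
        if e.event_type == "app_use"
    ]
    distinct = np.zeros(n_min)
    bag: dict[str, int] = {}
    a = b = 0
    for t in range(n_min):
        while b < len(app_events) and app_events[b][0] < t + hi_off:
            lbl = app_events[b][1]
            bag[lbl] = bag.get(lbl, 0) + 1
            b += 1
        while a < len(app_events) and app_events[a][0] < t + lo_off:
            lbl = app_events[a][1]
            bag[lbl] -= 1
            if not bag[lbl]:
                del bag[lbl]
            a += 1
        distinct[t] = len(bag)
    feats["n_distinct_apps"] = distinct

    # minutes since the most recent event of any type (capped at one day)
    any_event = np.zeros(n_min, dtype=bool)
    any_event[idx_all[(idx_all >= 0) & (idx_all < n_min)]] = True
    last = np.where(any_event, np.arange(n_min), -1)
    last = np.maximum.accumulate(last)
    since = np.where(last >= 0, np.arange(n_min) - last, MINUTES_PER_DAY)
    feats["minutes_since_last_event"] = np.minimum(
        since, MINUTES_PER_DAY
    ).astype(float)

    # screen state at the end of each minute, averaged over the window
    delta = counts["screen_on"] - counts["screen_off"]
    state = (np.cumsum(delta) > 0).astype(float)
    on_frac = window_sum(state) / cfg.window_minutes
    feats["screen_on_fraction"] = on_frac

    labels = work.minute_labels(start, n_min, tz).astype(int)
    step = timedelta(minutes=1)
    stamps = pd.date_range(start, periods=n_min, freq="min")
    df = pd.DataFrame(feats)
    df["label"] = labels
    df["minute_start"] = stamps
    df["date"] = [
        (start + timedelta(minutes=t)).astimezone(tz).date() for t in range(n_min)
    ]
    return df


@dataclass
class Stage1Result:
    series: WorkProbSeries
    model: XGBClassifier
    train_days: list[date]
    test_days: list[date]


def split_person_days(
    days: Sequence[date], ratio: float = 0.8, seed: int | None = None
) -> tuple[list[date], list[date]]:
    """Chronological person-day split: earliest fraction ``ratio`` trains.

    ``seed`` is accepted for interface uniformity; the split is
    deterministic (chronological) and never cuts within a day.
    """
    days = sorted(set(days))
    if len(days) < 2:
        raise ValidationError("need at least 2 person-days to split")
    n_train = int(ratio * len(days))
    n_train = min(max(n_train, 1), len(days) - 1)
    return days[:n_train], days[n_train:]


def stage1_train_predict(
    rows: pd.DataFrame,
    cfg: WmaConfig,
    usable_days: Sequence[date] | None = None,
    participant_id: str = "",
) -> Stage1Result:
    """Fit boosted trees on training person-days; predict all minutes.

    Rows outside ``usable_days`` (device-off days) are excluded from
    training and left missing in the output series.
    """
    all_days = sorted(rows["date"].unique())
    usable = sorted(usable_days) if usable_days is not None else all_days
    train_days, test_days = split_person_days(usable, cfg.split_ratio)
    train_mask = rows["date"].isin(train_days).to_numpy()
    y_train = rows.loc[train_mask, "label"].to_numpy()
    if np.unique(y_train).size < 2:
        raise ValidationError(
            f"participant {participant_id or rows.get('participant_id', '?')}: "
            "training days contain a single class"
        )
    model = XGBClassifier(
        n_estimators=cfg.xgb_estimators,
        max_depth=cfg.xgb_max_depth,
        learning_rate=cfg.xgb_learning_rate,
        random_state=cfg.seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    X = rows[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    model.fit(X[train_mask], y_train)
    probs = model.predict_proba(X)[:, 1].astype(float)
    usable_mask = rows["date"].isin(usable).to_numpy()
    probs[~usable_mask] = np.nan
    start = rows["minute_start"].iloc[0].to_pydatetime()
    series = WorkProbSeries(
        participant_id=participant_id,
        epoch_seconds=60,
        start=start,
        values=probs,
        label="WMA",
        stage="stage1",
    )
    return Stage1Result(series, model, list(train_days), list(test_days))


# ---------------------------------------------------------------------------
# WMA stage 2: run-length grayscale → images → convolutional classifier


def _runlength_block(p: np.ndarray, theta: float) -> np.ndarray:
    """L(t) = size of the maximal contiguous run containing t in which every
    value differs from p(t) by less than theta."""
    n = p.size
    cols = np.arange(n)
    within = np.abs(p[:, None] - p[None, :]) < theta  # rows: t, cols: s
    viol = ~within
    left = np.where(viol, cols[None, :], -1)
    left = np.maximum.accumulate(left, axis=1)  # nearest violation <= s
    right = np.where(viol, cols[None, :], n)
    right = np.minimum.accumulate(right[:, ::-1], axis=1)[:, ::-1]
    lv = left[cols, cols]
    rv = right[cols, cols]
    return (rv - lv - 1).astype(float)


def runlength_transform(
    p: np.ndarray | WorkProbSeries,
    theta: float,
    day_minutes: int = MINUTES_PER_DAY,
) -> np.ndarray:
    """Run-length grayscale of a probability series, in [0, 1].

    For each minute t, the run length L(t) is the size of the maximal
    contiguous run of minutes around t whose probabilities all differ from
    p(t) by less than ``theta``; runs are evaluated within calendar-day
    blocks and normalized by the day length, so g(t) = L(t)/day_minutes.
    Missing minutes break runs and stay missing.
    """
    if theta <= 0:
        raise ValidationError("theta must be positive")
    x = p.values if isinstance(p, WorkProbSeries) else np.asarray(p, dtype=float)
    out = np.full(x.size, np.nan)
    for lo in range(0, x.size, day_minutes):
        seg = x[lo : lo + day_minutes]
        finite = np.isfinite(seg)
        if not finite.any():
            continue
        # missing values break runs: process maximal finite sub-runs
        idx = np.flatnonzero(finite)
        splits = np.flatnonzero(np.diff(idx) > 1)
        for chunk in np.split(idx, splits + 1):
            g = _runlength_block(seg[chunk], theta)
            out[lo + chunk] = g / float(day_minutes)
    return out


def build_images(
    g: np.ndarray,
    cfg: WmaConfig,
    work_labels: np.ndarray | None = None,
):
    """Tile a minute-resolution grayscale series into stacked square images.

    Image k covers ``image_side`` consecutive ``image_unit_minutes``
    intervals (row r = the minutes of the r-th interval), advancing by
    ``image_stride_intervals`` intervals; its label is the majority work
    label of its final interval.  Images containing missing pixels are
    dropped.  Returns (images, labels_or_None, final_interval_starts).
    """
    unit = cfg.image_unit_minutes
    total = cfg.image_minutes
    stride = cfg.image_stride_intervals * unit
    n = g.size
    if n < total:
        warnings.warn("series shorter than one image; empty sequence", stacklevel=2)
        empty = np.empty((0, cfg.image_side, cfg.image_side))
        return empty, (np.empty(0, dtype=int) if work_labels is not None else None), np.empty(0, dtype=int)
    starts = np.arange(0, n - total + 1, stride)
    images, labels, finals = [], [], []
    for s in starts:
        window = g[s : s + total]
        if not np.all(np.isfinite(window)):
            continue
        images.append(window.reshape(cfg.image_side, unit))
        final_start = s + total - unit
        finals.append(final_start)
        if work_labels is not None:
            labels.append(int(work_labels[final_start : final_start + unit].mean() > 0.5))
    images = np.asarray(images) if images else np.empty((0, cfg.image_side, cfg.image_side))
    finals = np.asarray(finals, dtype=int)
    lab = np.asarray(labels, dtype=int) if work_labels is not None else None
    return images, lab, finals


def stage2_train(
    images: np.ndarray, labels: np.ndarray, cfg: WmaConfig
) -> SmallCnn:
    """Train the convolutional at-work / off-work classifier."""
    model = SmallCnn(
        image_side=cfg.image_side,
        seed=cfg.seed,
        epochs=cfg.cnn_epochs,
        batch_size=cfg.cnn_batch_size,
        learning_rate=cfg.cnn_learning_rate,
    )
    return model.fit(images, labels)


def _sequential_pass(
    values: np.ndarray,
    cfg: WmaConfig,
    emit,
    step_minutes: np.ndarray,
) -> np.ndarray:
    """Shared engine for sequential image-by-image emission.

    Slides forward one ``image_unit_minutes`` interval at a time; for each
    step whose final interval intersects ``step_minutes`` it assembles the
    run-length grayscale image of the preceding ``image_minutes`` minutes
    and calls ``emit(image, final_start) -> probability``.  With
    ``cfg.feedback`` the emitted hard decision overwrites the working
    series so later images see it in their look-back.  Returns the emitted
    minute-resolution series (NaN where nothing was emitted).
    """
    unit = cfg.image_unit_minutes
    total = cfg.image_minutes
    n = values.size
    working = values.copy()
    out = np.full(n, np.nan)

    gray: dict[int, np.ndarray] = {}
    dirty: set[int] = set()

    def day_gray(d: int) -> np.ndarray:
        if d not in gray or d in dirty:
            lo = d * MINUTES_PER_DAY
            gray[d] = runlength_transform(
                working[lo : lo + MINUTES_PER_DAY], cfg.runlength_threshold
            )
            dirty.discard(d)
        return gray[d]

    for final_start in range(total - unit, n - unit + 1, unit):
        if not step_minutes[final_start : final_start + unit].any():
            continue
        s = final_start + unit - total
        d0, d1 = s // MINUTES_PER_DAY, (s + total - 1) // MINUTES_PER_DAY
        g = np.concatenate([day_gray(d) for d in range(d0, d1 + 1)])[
            s - d0 * MINUTES_PER_DAY : s - d0 * MINUTES_PER_DAY + total
        ]
        if not np.all(np.isfinite(g)):
            continue
        prob = float(emit(g.reshape(cfg.image_side, unit), final_start))
        out[final_start : final_start + unit] = prob
        if cfg.feedback:
            # write back the hard decision, which stays within the
            # run-length threshold of confident stage-1 values and so
            # perturbs the grayscale minimally
            working[final_start : final_start + unit] = float(prob >= 0.5)
            dirty.add(final_start // MINUTES_PER_DAY)
    return out


def generate_wma(
    stage1: WorkProbSeries,
    model: SmallCnn,
    cfg: WmaConfig,
    predict_minutes: np.ndarray | None = None,
) -> WorkProbSeries:
    """Sequential work-mode probabilities from the stage-2 classifier.

    Sliding forward one ``image_unit_minutes`` interval at a time, the
    classifier probability of each image — whose look-back rows encode the
    previous probabilities in the sequence — is emitted for that image's
    final interval.  With ``cfg.feedback`` enabled, already-emitted
    decisions additionally replace stage-1 probabilities in the look-back
    portion of later images (off by default: output feedback through the
    run-length transform compounds its own errors; see the methods note).
    ``predict_minutes`` (boolean mask over the span) restricts which
    intervals are emitted; the output is minute resolution with the
    interval probability broadcast to its minutes, and missing wherever no
    prediction was made.
    """
    if not model.params:
        raise ConfigurationError("stage-2 model is not trained")
    if predict_minutes is None:
        predict_minutes = np.ones(stage1.n, dtype=bool)

    def emit(img: np.ndarray, final_start: int) -> float:
        return float(model.predict_proba(img[None, :, :])[0])

    out = _sequential_pass(stage1.values, cfg, emit, predict_minutes)
    return WorkProbSeries(
        participant_id=stage1.participant_id,
        epoch_seconds=60,
        start=stage1.start,
        values=out,
        label="WMA",
        stage="final",
    )


# ---------------------------------------------------------------------------
# evaluation and orchestration

MIN_LABELED_MINUTES = 2760


def evaluate_wma(
    pred: WorkProbSeries,
    truth: np.ndarray,
    threshold: float = 0.5,
    min_minutes: int = MIN_LABELED_MINUTES,
) -> dict[str, float]:
    """Minute-level accuracy, precision, recall, F1 and AUC.

    Only minutes with a nonmissing prediction are scored.  Participants
    with fewer than ``min_minutes`` labeled minutes are still scored, with
    a warning and ``flagged`` set in the result.
    """
    truth = np.asarray(truth).astype(int)
    if truth.size != pred.n:
        raise ValidationError("prediction and truth lengths differ")
    mask = np.isfinite(pred.values)
    y = truth[mask]
    p = pred.values[mask]
    if y.size == 0:
        raise ValidationError("no labeled minutes to evaluate")
    flagged = y.size < min_minutes
    if flagged:
        warnings.warn(
            f"only {y.size} labeled minutes (< {min_minutes}); metrics flagged",
            stacklevel=2,
        )
    yhat = (p >= threshold).astype(int)
    out = {
        "accuracy": float(skmetrics.accuracy_score(y, yhat)),
        "precision": float(
            skmetrics.precision_score(y, yhat, zero_division=0)
        ),
        "recall": float(skmetrics.recall_score(y, yhat, zero_division=0)),
        "f1": float(skmetrics.f1_score(y, yhat, zero_division=0)),
        "n_minutes": float(y.size),
        "flagged": float(flagged),
    }
    out["auc"] = (
        float(skmetrics.roc_auc_score(y, p)) if np.unique(y).size == 2 else float("nan")
    )
    return out


@dataclass
class WmaResult:
    stage1: Stage1Result
    final_series: WorkProbSeries
    stage2_model: SmallCnn
    truth: np.ndarray
    train_days: list[date]
    test_days: list[date]
    metrics: dict[str, float]


def fit_wma_participant(
    log: EventLog,
    work: WorkIntervalSet,
    cfg: WmaConfig,
    tz=None,
) -> WmaResult:
    """End-to-end per-participant WMA: features → stage 1 → images →
    stage 2 → sequential prediction on held-out days → metrics.

    Person-days with no recorded events are excluded from training and
    evaluation (device-off days).
    """
    tz = tz or (log.events[0].t.tzinfo if log.events else None)
    rows = stage1_features(log, work, cfg, tz)
    usable = log.dates(tz)
    span_days = sorted(rows["date"].unique())
    usable = [d for d in span_days if d in set(usable)]
    s1 = stage1_train_predict(rows, cfg, usable_days=usable, participant_id=log.participant_id)

    g = runlength_transform(s1.series, cfg.runlength_threshold)
    truth = rows["label"].to_numpy().astype(bool)
    images, labels, finals = build_images(g, cfg, work_labels=truth)
    # train on images whose final interval lies in a training day
    dates = rows["date"].to_numpy()
    train_set = set(s1.train_days)
    in_train = np.array([dates[f] in train_set for f in finals])
    x_train = images[in_train]
    y_train = labels[in_train]
    if x_train.shape[0] == 0 or np.unique(y_train).size < 2:
        raise ValidationError(
            f"participant {log.participant_id}: stage-2 training images "
            "contain a single class"
        )
    model2 = stage2_train(x_train, y_train, cfg)

    test_set = set(s1.test_days)
    predict_mask = np.array([d in test_set for d in dates])
    final = generate_wma(s1.series, model2, cfg, predict_minutes=predict_mask)
    # score test-day minutes only
    scored = WorkProbSeries(
        participant_id=final.participant_id,
        epoch_seconds=60,
        start=final.start,
        values=np.where(predict_mask, final.values, np.nan),
        label="WMA",
        stage="final",
    )
    mets = evaluate_wma(scored, truth)
    return WmaResult(
        stage1=s1,
        final_series=final,
        stage2_model=model2,
        truth=truth,
        train_days=s1.train_days,
        test_days=s1.test_days,
        metrics=mets,
    )
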