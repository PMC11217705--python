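"""GMA epoching and the two-stage WMA model."""

from __future__ import annotations

from datetime import date, datetime, time, timedelta, timezone
from zoneinfo import ZoneInfo

import numpy as np
import pytest

from rhythmkit.errors import ConfigurationError, ValidationError
from rhythmkit.io_events import Event, EventLog, WorkInterval, WorkIntervalSet
from rhythmkit.mental_activity import (
    EPOCHS_PER_DAY_5MIN,
    FEATURE_COLUMNS,
    WmaConfig,
    WorkProbSeries,
    app_counts,
    build_images,
    evaluate_wma,
    fit_wma_participant,
    generate_wma,
    runlength_transform,
    split_person_days,
    stage1_features,
    stage1_train_predict,
    stage2_train,
    use_counts,
)

UTC = timezone.utc
DAY = date(2023, 1, 2)
T0 = datetime(2023, 1, 2, 0, 0, tzinfo=UTC)


# --- GMA --------------------------------------------------------------------


def test_use_counts_minute_histogram():
    events = [
        Event(T0 + timedelta(minutes=3, seconds=10), "app_use", "a"),
        Event(T0 + timedelta(minutes=3, seconds=50), "app_use", "b"),
        Event(T0 + timedelta(minutes=7), "app_use", "a"),
        Event(T0 + timedelta(minutes=9), "notification", "a"),  # not counted
        Event(T0 + timedelta(minutes=11), "screen_on", None),  # not counted
    ]
    log = EventLog.from_events("p1", events)
    s = use_counts(log, DAY, UTC)
    assert s.n == 1440
    assert s.values[3] == 2 and s.values[7] == 1
    assert s.values.sum() == 3


def test_empty_day_all_missing_never_zero():
    log = EventLog("p1", ())
    s = use_counts(log, DAY, UTC)
    assert np.isnan(s.values).all()


def test_app_counts_288_epochs_per_day():
    vals = np.ones(1440)
    s = use_counts(EventLog("p1", ()), DAY, UTC).with_values(vals)
    epochs = app_counts(s)
    assert epochs.n == EPOCHS_PER_DAY_5MIN
    np.testing.assert_array_equal(epochs.values, 5.0)


def test_app_counts_missing_rule():
    vals = np.zeros(1440)
    vals[0:5] = np.nan  # all 5 missing → epoch missing
    vals[5] = np.nan    # 1 of 5 missing → epoch = sum of the rest
    vals[6:10] = 2.0
    s = use_counts(EventLog("p1", ()), DAY, UTC).with_values(vals)
    epochs = app_counts(s)
    assert np.isnan(epochs.values[0])
    assert epochs.values[1] == 8.0


def test_app_counts_rejects_unaligned_start():
    s = use_counts(EventLog("p1", ()), DAY, UTC)
    shifted = type(s)(
        participant_id="p1",
        epoch_seconds=60,
        start=T0 + timedelta(minutes=2),
        values=np.zeros(100),
        label="GMA",
    )
    with pytest.raises(ValidationError, match="5-minute boundary"):
        app_counts(shifted)


# --- config -----------------------------------------------------------------


def test_config_validation():
    with pytest.raises(ValidationError):
        WmaConfig(split_ratio=1.0)
    with pytest.raises(ValidationError):
        WmaConfig(runlength_threshold=0.0)
    with pytest.raises(ConfigurationError, match="small_cnn"):
        WmaConfig(cnn_arch="resnet34")


def test_workprob_range_enforced():
    with pytest.raises(ValidationError, match=r"\[0, 1\]"):
        WorkProbSeries(
            participant_id="p1", epoch_seconds=60, start=T0,
            values=np.array([0.5, 1.5]), label="WMA",
        )


# --- stage-1 features -------------------------------------------------------


def brute_force_features(log, cfg, start, n_min):
    """Per-minute recount of every feature by direct event scanning."""
    half = cfg.window_minutes // 2
    lo_off, hi_off = -half, cfg.window_minutes - half
    out = {c: np.zeros(n_min) for c in FEATURE_COLUMNS}
    minutes = [
        int((e.t - start).total_seconds() // 60) for e in log.events
    ]
    # screen state at each minute start
    state = np.zeros(n_min)
    on = 0
    per_min = {}
    for m, e in zip(minutes, log.events):
        per_min.setdefault(m, []).append(e)
    for t in range(n_min):
        for e in per_min.get(t, []):
            if e.event_type == "screen_on":
                on += 1
            elif e.event_type == "screen_off":
                on -= 1
        state[t] = 1.0 if on > 0 else 0.0  # state at the end of minute t
    for t in range(n_min):
        w = [
            e
            for m, e in zip(minutes, log.events)
            if t + lo_off <= m < t + hi_off
        ]
        out["n_screen_on"][t] = sum(e.event_type == "screen_on" for e in w)
        out["n_screen_off"][t] = sum(e.event_type == "screen_off" for e in w)
        out["n_notification"][t] = sum(e.event_type == "notification" for e in w)
        out["n_app_use"][t] = sum(e.event_type == "app_use" for e in w)
        out["n_distinct_apps"][t] = len(
            {e.app_label for e in w if e.event_type == "app_use"}
        )
        past = [m for m in minutes if m <= t]
        out["minutes_since_last_event"][t] = (
            min(t - max(past), 1440) if past else 1440
        )
        lo = max(t + lo_off, 0)
        hi = min(t + hi_off, n_min)
        out["screen_on_fraction"][t] = state[lo:hi].sum() / cfg.window_minutes
    return out


def test_stage1_features_window_oracle():
    rng = np.random.default_rng(17)
    cfg = WmaConfig()
    events = []
    n_min = 1440
    on = False
    for t in range(0, n_min, 1):
        u = rng.uniform()
        if not on and u < 0.05:
            on = True
            events.append(Event(T0 + timedelta(minutes=t, seconds=1), "screen_on", None))
        elif on and u < 0.12:
            on = False
            events.append(Event(T0 + timedelta(minutes=t, seconds=2), "screen_off", None))
        for _ in range(rng.poisson(0.15)):
            events.append(
                Event(
                    T0 + timedelta(minutes=t, seconds=float(rng.uniform(0, 60))),
                    "app_use",
                    f"app{rng.integers(4)}",
                )
            )
        if rng.uniform() < 0.03:
            events.append(
                Event(
                    T0 + timedelta(minutes=t, seconds=30.0),
                    "notification",
                    f"app{rng.integers(4)}",
                )
            )
    log = EventLog.from_events("p1", events)
    work = WorkIntervalSet("p1", (WorkInterval(DAY, time(9), time(17, 30)),))
    rows = stage1_features(log, work, cfg, UTC)
    assert rows.shape[0] == n_min
    expect = brute_force_features(log, cfg, T0, n_min)
    for col in FEATURE_COLUMNS:
        np.testing.assert_allclose(
            rows[col].to_numpy(), expect[col], err_msg=col, atol=1e-12
        )
    np.testing.assert_array_equal(
        rows["label"].to_numpy(),
        work.minute_labels(T0, n_min, UTC).astype(int),
    )


def test_stage1_features_empty_log_rejected():
    work = WorkIntervalSet("p1", ())
    with pytest.raises(ValidationError, match="zero usable minutes"):
        stage1_features(EventLog("p1", ()), work, WmaConfig(), UTC)


# --- person-day split -------------------------------------------------------


def test_split_floor_and_clamp():
    days = [DAY + timedelta(days=i) for i in range(10)]
    train, test = split_person_days(days, 0.8)
    assert len(train) == 8 and len(test) == 2
    assert max(train) < min(test)  # chronological
    train, test = split_person_days(days[:2], 0.8)
    assert len(train) == 1 and len(test) == 1
    train, test = split_person_days(days, 0.05)  # floor would give 0 → clamp
    assert len(train) == 1
    train, test = split_person_days(days, 0.99)  # floor gives 9 → test keeps 1
    assert len(test) == 1


def test_split_rejects_single_day():
    with pytest.raises(ValidationError, match="at least 2"):
        split_person_days([DAY])


# --- run-length transform ---------------------------------------------------


def brute_force_runlength(p, theta, day_minutes=1440):
    """Bidirectional scan oracle: for each t, extend left and right while
    every value in the run stays within theta of p[t]."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.size, np.nan)
    for lo in range(0, p.size, day_minutes):
        seg = p[lo : lo + day_minutes]
        for t in range(seg.size):
            if not np.isfinite(seg[t]):
                continue
            left = t
            while left - 1 >= 0 and np.isfinite(seg[left - 1]) and abs(seg[left - 1] - seg[t]) < theta:
                left -= 1
            right = t
            while right + 1 < seg.size and np.isfinite(seg[right + 1]) and abs(seg[right + 1] - seg[t]) < theta:
                right += 1
            out[lo + t] = (right - left + 1) / day_minutes
    return out


def test_runlength_oracle_random():
    rng = np.random.default_rng(23)
    for _ in range(10):
        n = int(rng.integers(50, 400))
        p = rng.uniform(size=n)
        p[rng.uniform(size=n) < 0.05] = np.nan
        got = runlength_transform(p, 0.1, day_minutes=200)
        np.testing.assert_allclose(got, brute_force_runlength(p, 0.1, 200))


def test_runlength_constant_run():
    p = np.array([0.9] * 5 + [0.1] * 3)
    g = runlength_transform(p, 0.1, day_minutes=8)
    np.testing.assert_allclose(g, [5 / 8] * 5 + [3 / 8] * 3)


def test_runlength_day_blocks_independent():
    p = np.array([0.5] * 6)
    g = runlength_transform(p, 0.1, day_minutes=3)
    np.testing.assert_allclose(g, 1.0)  # each 3-minute "day" is a full run


def test_runlength_requires_positive_theta():
    with pytest.raises(ValidationError, match="theta"):
        runlength_transform(np.zeros(5), 0.0)


# --- images -----------------------------------------------------------------


def test_build_images_geometry():
    cfg = WmaConfig(image_side=4, image_unit_minutes=4, image_stride_intervals=1)
    g = np.arange(40, dtype=float) / 40.0
    labels = np.zeros(40, dtype=int)
    labels[20:] = 1
    images, labs, finals = build_images(g, cfg, labels)
    # total = 16 minutes, stride = 4 → starts 0,4,...,24 → 7 images
    assert images.shape == (7, 4, 4)
    np.testing.assert_array_equal(finals, np.arange(12, 40 - 4 + 1, 4))
    np.testing.assert_array_equal(images[0], g[:16].reshape(4, 4))
    # label = majority of final interval
    np.testing.assert_array_equal(labs, (finals + 2 >= 20).astype(int))


def test_build_images_drops_missing():
    cfg = WmaConfig(image_side=4, image_unit_minutes=4)
    g = np.ones(40)
    g[18] = np.nan
    images, _, finals = build_images(g, cfg, np.zeros(40, dtype=int))
    # windows covering minute 18 (starts 4..16) are dropped
    assert 18 not in [f for s in finals for f in range(s - 12, s + 4)]
    assert np.isfinite(images).all()


def test_build_images_short_series_warns():
    cfg = WmaConfig(image_side=4, image_unit_minutes=4)
    with pytest.warns(UserWarning, match="shorter"):
        images, labs, finals = build_images(np.ones(10), cfg, np.zeros(10, dtype=int))
    assert images.shape[0] == 0 and finals.size == 0


# --- end-to-end WMA ---------------------------------------------------------


@pytest.fixture(scope="module")
def wma_fit(one_participant):
    cfg = WmaConfig(seed=0)
    return fit_wma_participant(
        one_participant.event_log,
        one_participant.work_intervals,
        cfg,
        ZoneInfo("Asia/Taipei"),
    )


def test_wma_end_to_end_quality(wma_fit):
    assert wma_fit.metrics["auc"] >= 0.9
    assert wma_fit.metrics["accuracy"] >= 0.85


def test_wma_split_chronological(wma_fit):
    assert len(wma_fit.train_days) == 8 and len(wma_fit.test_days) == 2
    assert max(wma_fit.train_days) < min(wma_fit.test_days)


def test_wma_predictions_only_on_test_days(wma_fit, one_participant):
    tz = ZoneInfo("Asia/Taipei")
    final = wma_fit.final_series
    have = np.isfinite(final.values)
    idx = np.flatnonzero(have)
    span_start = final.start
    days = {
        (span_start + timedelta(minutes=int(i))).astimezone(tz).date()
        for i in idx
    }
    assert days <= set(wma_fit.test_days)


def test_wma_probabilities_valid(wma_fit):
    v = wma_fit.final_series.values
    fin = v[np.isfinite(v)]
    assert fin.size > 0
    assert fin.min() >= 0.0 and fin.max() <= 1.0
    # minute probabilities are constant within each 30-minute interval
    assert wma_fit.final_series.stage == "final"


def test_generate_wma_deterministic(wma_fit):
    cfg = WmaConfig(seed=0)
    s1 = wma_fit.stage1.series
    a = generate_wma(s1, wma_fit.stage2_model, cfg)
    b = generate_wma(s1, wma_fit.stage2_model, cfg)
    np.testing.assert_array_equal(a.values, b.values)


def test_generate_wma_untrained_rejected(wma_fit):
    from rhythmkit.cnn import SmallCnn

    with pytest.raises(ConfigurationError, match="not trained"):
        generate_wma(wma_fit.stage1.series, SmallCnn(), WmaConfig())


def test_evaluate_flags_short_records():
    vals = np.full(3000, np.nan)
    vals[:100] = 0.9
    pred = WorkProbSeries(
        participant_id="p1", epoch_seconds=60, start=T0,
        values=vals, label="WMA", stage="final",
    )
    truth = np.zeros(3000, dtype=int)
    truth[:100] = 1
    with pytest.warns(UserWarning, match="flagged"):
        m = evaluate_wma(pred, truth)
    assert m["flagged"] == 1.0
    assert m["accuracy"] == 1.0


def test_evaluate_confusion_matrix_oracle():
    vals = np.array([0.9, 0.8, 0.2, 0.4, 0.6, np.nan])
    truth = np.array([1, 0, 0, 1, 1, 1])
    pred = WorkProbSeries(
        participant_id="p1", epoch_seconds=60, start=T0,
        values=vals, label="WMA", stage="final",
    )
    with pytest.warns(UserWarning):
        m = evaluate_wma(pred, truth)
    # yhat = 1,1,0,0,1 vs y = 1,0,0,1,1 → tp=2 fp=1 tn=1 fn=1
    assert m["accuracy"] == pytest.approx(3 / 5)
    assert m["precision"] == pytest.approx(2 / 3)
    assert m["recall"] == pytest.approx(2 / 3)
    assert m["f1"] == pytest.approx(2 / 3)
    assert m["n_minutes"] == 5.0
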