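# Methods

This note records the methodological choices made in `rhythmkit`, the
reasoning behind them, and the conventions a user needs to interpret the
outputs. All defaults named here are the values shipped in the package;
each is configurable unless stated otherwise.

## 1. Acti-counts from raw acceleration (`actigraphy.accel_to_acticounts`)

Per-minute acti-counts are computed from a triaxial trace in five stages:

1. **Gravity removal** — per-axis running median over a 5-second window,
   subtracted from the signal. A running median tracks slow orientation
   changes without ringing at posture shifts.
2. **Magnitude** — Euclidean norm of the three residual axes.
3. **Band-pass** — zero-phase Butterworth (order 4, applied
   forward–backward with `sosfiltfilt`) over 0.5–3 Hz, the band of
   voluntary human movement; this rejects residual drift and high-
   frequency sensor noise. The sampling rate must exceed twice the band
   top (Nyquist guard).
4. **Threshold** — magnitudes below 0.01 g are zeroed. The threshold (in
   g) and the band are **not identifiable from counts alone**: different
   (threshold, gain) pairs can produce proportional count series, and
   commercial devices do not disclose theirs. Count units are therefore
   arbitrary device units; all downstream statistics (Cole–Kripke
   scoring, M10 comparisons, phase) are either scale-calibrated or
   scale-free, and the threshold is exposed as a parameter rather than
   presented as a calibrated constant.
5. **Integration** — supra-threshold magnitude is integrated over
   2-second segments (g·s), and the 30 segment integrals within each
   minute are averaged to give that minute's count.

## 2. Sleep scoring (`actigraphy.cole_kripke_score`, `score_nights`)

Minute-level sleep/wake labels use the Cole–Kripke weighted sum over a
7-minute window (4 minutes back, the current minute, 2 forward):

    D = 0.001 · (106·A₋₄ + 54·A₋₃ + 58·A₋₂ + 76·A₋₁ + 230·A₀ + 74·A₊₁ + 67·A₊₂)

with *sleep* iff `D < 1`. The published minute-scale coefficients are the
default; the weights and scale are configurable because devices differ in
count calibration (see §1). Missing minutes contribute zero to the sum
and propagate a missing-label mask.

**Night convention.** Nights are noon-to-noon local windows, attributed
to the calendar date of the evening half: a sleep onset at 00:40 on
Jan 6 belongs to the night of Jan 5. Within a window, the main sleep
episode is the longest run of sleep-labeled minutes after bridging awake
interruptions of ≤ 15 minutes; onset and wake are its endpoints, total
sleep time (TST) counts sleep-labeled minutes inside them, and the
midpoint is expressed in hours since the night date's local midnight
(03:15 → 27.25), which keeps the midpoint axis continuous across
midnight. Nights with < 180 minutes of sleep or > 20% missing labels are
flagged and carry null indicators.

## 3. General mental activity (`mental_activity.use_counts`, `app_counts`)

App-use events are binned into per-minute counts over one local calendar
day, then aggregated into five-minute epochs — exactly 288 per day, a
fixed grid chosen so that day-level statistics never mix partial epochs.
A day with no events at all is treated as device-off: all 288 epochs are
missing (not zero), and such days are excluded from model training and
evaluation.

## 4. Working mental activity: the two-stage model

### Stage 1 — minute-level work probability (`stage1_train_predict`)

A gradient-boosted tree classifier (XGBoost; 100 trees, depth 4,
learning rate 0.2) predicts per-minute work state from seven features
computed over a trailing 10-minute window ending at (and including) the
current minute: app-use event count, distinct apps used, notification
count, unlock count, screen-on fraction (screen state evaluated at the
end of each minute, averaged over the window), minutes since the last
interaction, and local hour-of-day. Labels for training come from
declared work intervals. Days are split chronologically — the first 80%
of a participant's person-days train, the rest are held out — because
interaction behavior is autocorrelated within a day and a random
minute-level split would leak.

### Run-length transform (`runlength_transform`)

Stage-1 probabilities are mapped to a grayscale encoding of *persistence*:
for each minute with probability ≥ θ (default θ = 0.1), the value is the
length of the maximal contiguous run of supra-threshold minutes
containing it, divided by the minutes per day (1440); sub-threshold
minutes are 0. Normalizing by the day length bounds the encoding in
[0, 1] and makes it invariant to the epoch bookkeeping. The transform is
applied per day so runs never span midnight. The small θ deliberately
keeps low-confidence but persistent episodes visible: persistence, not
instantaneous confidence, is what distinguishes work from casual use.

### Stage 2 — interval-level CNN (`build_images`, `SmallCnn`)

The grayscale minute series is folded into 30×30 images: 30 rows of 30
minutes, i.e. 15 hours ending at the interval being classified, built at
a stride of one 30-minute interval. The label of an image is the
majority work state of its final interval. A small convolutional network
(one conv layer, 2×2 max-pool, one hidden dense layer, sigmoid output)
implemented in pure numpy is trained with mini-batch gradient descent;
its correctness is pinned by numerical-gradient tests. At inference the
model emits one work probability per interval, sequentially in time.

**Static look-back.** An autoregressive variant — writing each emitted
hard decision back into the look-back of later images — was implemented
and measured (with and without teacher-forced training, with soft and
hard write-back). Output feedback through the look-back was unstable:
early errors propagate and saturate whole days. The default therefore
keeps the look-back fixed at the stage-1 probabilities
(`WmaConfig.feedback = False`); the feedback variant remains available
behind the flag.

**Per-participant models.** Both stages are fit per participant. Work
schedules, app repertoires and baseline interaction rates differ enough
between people that a pooled model mostly learns the cohort schedule;
per-participant fitting is also what makes the held-out AUC a meaningful
individual metric.

## 5. Rhythm metrics

### M10 (`rhythm.m10`)

For one local calendar day, M10 is the maximum over all 10-hour windows
(at the series' epoch resolution, windows starting within the day and
lying fully inside it — windows do not cross midnight) of the mean
activity in the window, ignoring missing epochs; ties resolve to the
earliest window. Days with < 80% epoch coverage are flagged. The value
and the window onset time are both reported.

### Circadian band filter (`rhythm.circadian_filter`)

Signals are zero-meaned and band-passed to 16–28-hour periods with an
order-2 Butterworth filter applied forward–backward (`sosfiltfilt`), so
the filter is zero-phase by construction — essential, since the
quantity of interest *is* phase. The effective amplitude response is
|H(f)|²; the filter contract (unity ±10% at 24 h, ≥ 20 dB attenuation at
6 h) is enforced by tests against the analytic response. At least ~4
days of data are required for the band to be resolvable; shorter series
are rejected.

### Phase and phase differences (`rhythm.hilbert_phase`, `phase_difference`)

The instantaneous phase is the argument of the analytic signal
x + i·H[x]; for a cosine it is 0 at each peak and advances 2π per cycle.
Phase differences between a target and a reference signal are averaged
**circularly** (argument of the mean resultant of e^{iΔφ}), never
arithmetically — arithmetic means are wrong near the ±π wrap. The first
and last 12 hours of the phase series are trimmed before averaging,
because the Hilbert transform (and the double-pass filter) are biased at
the series edges.

**Sign convention.** For a rhythm *delayed* by δ hours relative to the
reference, the instantaneous phase difference Δφ = φ_target − φ_reference
is *negative* (the target has accumulated less phase). Two fields are
reported: `mean_diff_hours`, the plain unit conversion of the circular
mean (π/2 rad ↔ 6 h); and `target_delay_hours = −mean_diff_hours`
(re-wrapped to (−12, 12]), which is positive when the target trails the
reference and is the field to use when the question is "by how many
hours does signal B lag signal A?".

### Resampling and imputation (`rhythm.to_epoch`, `impute_missing`)

Phase analysis uses a common 5-minute grid: per-minute series are
mean-aggregated (a coarse epoch is missing only if all constituent fine
epochs are). Remaining missing epochs are filled by resampling observed
values with replacement (deterministic under the pipeline seed) — a
choice that adds no spurious rhythmicity, unlike interpolation, at the
cost of some broadband noise which the band filter removes.

## 6. Day-level association (`association`)

`build_day_table` pairs each day's M10 (per signal) with the **previous
night's** sleep indicators; a day whose preceding night is absent or
flagged is dropped (and counted), and a flagged M10 becomes a missing
outcome, not a dropped row. Each row also carries age, gender and a
workday indicator derived from declared work intervals.

`fit_multilevel` fits, by REML, a two-level linear model with a random
intercept per participant:

    m10 ~ sleep_midpoint_prev_h + tst_prev_min + gender + age + (1 | participant)

Implementation notes:

- **Conditioning.** Predictors are z-scored internally before fitting and
  coefficients, standard errors and confidence intervals are transformed
  back exactly afterwards; this is an affine reparameterization that
  leaves inference invariant but avoids the singular Hessians the
  optimizer encounters on raw scales (minutes vs. hours vs. years).
  A fallback chain of optimizers (lbfgs → powell → cg → nm) is tried.
- **Constant predictors** (e.g. a single-gender cohort) are dropped from
  the design and reported as NaN fixed effects rather than crashing or
  silently absorbing into the intercept.
- **Inference.** Wald z confidence intervals and p-values are reported.
  Small-sample degrees-of-freedom corrections (e.g. Satterthwaite) are
  not provided by the backend; with cohorts of ~24 participants × ~19
  days the large-sample approximation is adequate, and the fit is
  verified against an independent R/lme4 REML oracle in the test suite.
- Standardized coefficients (per SD of predictor, per SD of outcome) are
  reported alongside raw ones.

## 7. Synthetic cohort (`synthetic`)

The generator produces, per participant: a per-minute acti-count series,
an app-event log (app-use, notification, screen and unlock events with
regime-dependent rates), declared work intervals (Mon–Fri, 09:00–17:30
with schedule jitter), demographics, and the full ground truth
(sleep windows and minutes, work-minute labels, excluded days). Design
points:

- **Regimes.** Each minute is in exactly one of sleep / work / leisure;
  event rates differ by regime (work has strongly elevated interaction
  rates — the "strong contrast" default), and acti-counts are near zero
  during sleep.
- **Rhythm structure.** The underlying PA rate is a 24-hour profile;
  GMA and WMA rate profiles are the same shape shifted by +73 and −65
  minutes respectively, so phase-difference recovery has a known truth.
- **Sleep → next-day coupling.** The PA amplitude of day *d* is scaled by
  exp(effects) of the previous night's standardized sleep midpoint and
  TST (defaults: β_midpoint = −0.3 per SD, β_TST = 0) plus a participant
  random intercept and day-level noise, giving the mixed model a known
  estimand. `simulate_day_table` exposes the same estimand in closed
  form (per-hour truth = β / midpoint SD) for fast large-replicate
  checks of CI coverage.
- **Device-off days.** Each person-day is dropped entirely with 5%
  probability: no events, missing counts — exercising the missing-data
  paths end to end.
- **Limitations.** Event streams are conditionally Poisson within
  regime, sleep is consolidated (no naps), weekends have no work, and
  acceleration is generated at the count level, not the raw-signal
  level, except in dedicated acti-count tests. These simplifications are
  deliberate: the generator's job is known ground truth under the study
  conditions, not behavioral realism.

The generator defaults are the study conditions; tests and acceptance
checks run against them unmodified.

## 8. Verification design (tests & `scripts/acceptance.py`)

Quantitative claims are tested against independent oracles wherever one
exists: brute-force re-implementations (Cole–Kripke scoring, M10 window
scan, run-length transform, stage-1 features), analytic references (the
Butterworth amplitude response, measured by lock-in projection at the
driving frequency), scipy (t-tests, skewness/kurtosis), R/lme4 (the
mixed model), and generator ground truth (sleep, phase lags, the
association β, WMA labels). Two statistical details are worth recording:

- **Permutation null for the WMA classifier.** Stage-2 images are built
  at stride 1, so neighboring images overlap 29/30 and are strongly
  dependent; a null design that permutes only training labels and scores
  against true held-out labels violates the independence assumptions of
  a binomial band and produced wildly variable "null" accuracies. The
  null therefore balances classes by subsampling (making 0.5 the chance
  level), permutes labels over the *entire* balanced set before the
  train/test split (so held-out labels are exchangeable and independent
  of the images), and pools several permutation rounds before applying
  the binomial band at the pooled sample size.
- **Coverage checks.** CI coverage of the association β is assessed over
  many generator seeds at the default scale, with the nominal 95% band
  relaxed only for Monte-Carlo error at the replicate count used.
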