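"""Day-level statistics: group comparisons and the two-level sleep→activity model.

The core model predicts a day's activity level (M10 of PA, GMA or WMA) from
the previous night's sleep (total sleep time and midpoint of sleep) while
controlling for gender and age, with days nested in participants:

    m10_{id} = β0 + β1·midpoint_{id} + β2·tst_{id} + β3·gender_i + β4·age_i
               + u_i + ε_{id},   u_i ~ N(0, τ²),  ε_{id} ~ N(0, σ²)

fit by restricted maximum likelihood.  Gender is dummy-coded 1 = male,
2 = female; the sleep midpoint is on a continuous hour axis that crosses
midnight (03:00 → 27.0).  Coefficients are reported both raw and with
standardized (z-scored) outcome and continuous predictors, since either
scaling is common in day-level diary studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from rhythmkit.errors import ValidationError
from rhythmkit.io_events import DAY_TABLE_COLUMNS, validate_day_table
from rhythmkit.actigraphy import SleepRecord
from rhythmkit.rhythm import M10Result

PREDICTORS = ("midpoint_of_sleep", "total_sleep_time", "gender", "age")


@dataclass(frozen=True)
class ComparisonResult:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    paired: bool


@dataclass(frozen=True)
class FixedEffect:
    beta: float
    se: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MixedModelResult:
    outcome: str
    fixed_effects: Mapping[str, FixedEffect]
    fixed_effects_std: Mapping[str, FixedEffect]
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_participants: int
    converged: bool
    boundary: bool  # random-intercept variance pinned at (near) zero


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
) -> ComparisonResult:
    """Welch two-sample (default) or paired t test, two-sided."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if paired:
        if a.size != b.size:
            raise ValidationError("paired comparison requires equal lengths")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        paired=paired,
    )


def screen_distribution(values: Sequence[float]) -> dict[str, float]:
    """Skewness and (Fisher) excess kurtosis screening for day-level variables."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return {
        "skewness": float(stats.skew(v)),
        "kurtosis": float(stats.kurtosis(v, fisher=True)),
        "n": int(v.size),
    }


def build_day_table(
    m10_results: Mapping[str, Sequence[M10Result]],
    sleep_records: Sequence[SleepRecord],
    work_dates: Mapping[str, set],
    demographics: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Join day-level activity with the previous night's sleep.

    ``m10_results`` maps "PA"/"GMA"/"WMA" to per-participant-day results;
    day *d* is paired with the sleep record of the night starting on
    *d − 1 day* (the night ending on the morning of *d*).  ``work_dates``
    maps participant id to the set of dates with any work interval.
    ``demographics`` has columns participant_id, gender_code, age_years.
    Rows with a missing outcome or any missing predictor are dropped;
    returns (table, n_dropped).
    """
    sleep_by_key = {
        (r.participant_id, r.night_date): r for r in sleep_records
    }
    demo = demographics.set_index("participant_id")
    by_key: dict[tuple[str, date], dict] = {}
    for label, results in m10_results.items():
        col = f"m10_{label.lower()}"
        for r in results:
            row = by_key.setdefault((r.participant_id, r.date), {})
            row[col] = r.m10_value if not r.flagged else np.nan

    rows = []
    n_dropped = 0
    for (pid, d), vals in sorted(by_key.items()):
        rec = sleep_by_key.get((pid, d - timedelta(days=1)))
        if rec is None or rec.flagged:
            n_dropped += 1
            continue
        if pid not in demo.index:
            n_dropped += 1
            continue
        full = {
            "participant_id": pid,
            "date": d,
            "is_workday": d in work_dates.get(pid, set()),
            "m10_pa": vals.get("m10_pa", np.nan),
            "m10_gma": vals.get("m10_gma", np.nan),
            "m10_wma": vals.get("m10_wma", np.nan),
            "tst_prev_min": rec.total_sleep_time_min,
            "sleep_midpoint_prev_h": rec.midpoint_h,
            "gender_code": int(demo.loc[pid, "gender_code"]),
            "age_years": float(demo.loc[pid, "age_years"]),
        }
        rows.append(full)
    table = pd.DataFrame(rows, columns=list(DAY_TABLE_COLUMNS))
    return validate_day_table(table), n_dropped


def _fit_one(df: pd.DataFrame, outcome: str) -> tuple[dict[str, FixedEffect], float, float, bool]:
    """REML fit with internally centered/scaled predictors.

    Raw-scale predictors (TST in minutes, age in years) are badly
    conditioned for the profiled-likelihood optimizers, so the design is
    z-scored before fitting and the coefficients, standard errors and
    intervals are transformed back exactly; inference is invariant to this
    affine reparameterization.
    """
    work = df.copy()
    means: dict[str, float] = {}
    scales: dict[str, float] = {}
    active: list[str] = []
    for col in PREDICTORS:
        m = float(work[col].mean())
        s = float(work[col].std(ddof=1))
        if not np.isfinite(s) or s <= 0:
            # a constant covariate (e.g. single-gender cohort) is confounded
            # with the intercept and not estimable; drop it from the design
            means[col], scales[col] = m, 1.0
            continue
        means[col], scales[col] = m, s
        work[col] = (work[col] - m) / s
        active.append(col)
    if not active:
        raise ValidationError("all predictors are constant; model unidentified")
    model = smf.mixedlm(
        f"{outcome} ~ {' + '.join(active)}",
        data=work,
        groups=work["participant_id"],
    )
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (["lbfgs", "powell"], ["cg"], ["nm"]):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if fit is None:
        raise ValidationError("mixed model estimation failed for all optimizers")

    zcrit = float(stats.norm.ppf(0.975))
    fe = {}
    for name in PREDICTORS:
        if name not in active:
            fe[name] = FixedEffect(np.nan, np.nan, np.nan, np.nan, np.nan)
            continue
        b = float(fit.params[name]) / scales[name]
        se = float(fit.bse[name]) / scales[name]
        fe[name] = FixedEffect(
            beta=b,
            se=se,
            p_value=float(fit.pvalues[name]),
            ci_low=b - zcrit * se,
            ci_high=b + zcrit * se,
        )
    # intercept on the original scale: linear combination of fitted params
    names = ("Intercept",) + tuple(active)
    c = np.array([1.0] + [-means[n] / scales[n] for n in active])
    params = np.array([float(fit.params[n]) for n in names])
    cov = fit.cov_params().loc[list(names), list(names)].to_numpy()
    b0 = float(c @ params)
    se0 = float(np.sqrt(c @ cov @ c))
    z0 = b0 / se0 if se0 > 0 else np.inf
    fe["Intercept"] = FixedEffect(
        beta=b0,
        se=se0,
        p_value=float(2.0 * stats.norm.sf(abs(z0))),
        ci_low=b0 - zcrit * se0,
        ci_high=b0 + zcrit * se0,
    )
    tau2 = float(fit.cov_re.iloc[0, 0])
    sigma2 = float(fit.scale)
    return fe, tau2, sigma2, bool(fit.converged)


def fit_multilevel(
    table: pd.DataFrame,
    outcome: str,
) -> MixedModelResult:
    """Random-intercept model of a day's M10 on the previous night's sleep.

    Level 1 (within person): sleep midpoint and total sleep time of the
    previous night; Level 2 (between person): gender and age.  REML
    estimation; Wald z p-values and confidence intervals.  A singular
    (boundary) random-intercept fit is returned flagged, not raised.
    """
    if outcome not in ("m10_pa", "m10_gma", "m10_wma"):
        raise ValidationError(f"unknown outcome {outcome!r}")
    df = table.dropna(
        subset=[outcome, "tst_prev_min", "sleep_midpoint_prev_h", "gender_code", "age_years"]
    ).copy()
    counts = df.groupby("participant_id").size()
    if (counts >= 2).sum() < 2:
        raise ValidationError("need >= 2 participants with >= 2 days each")
    df = df.rename(
        columns={
            "sleep_midpoint_prev_h": "midpoint_of_sleep",
            "tst_prev_min": "total_sleep_time",
            "gender_code": "gender",
            "age_years": "age",
        }
    )
    fe_raw, tau2, sigma2, conv = _fit_one(df, outcome)

    dfz = df.copy()
    for col in (outcome, "midpoint_of_sleep", "total_sleep_time", "age"):
        sd = dfz[col].std(ddof=1)
        dfz[col] = (dfz[col] - dfz[col].mean()) / (sd if sd > 0 else 1.0)
    fe_std, _, _, _ = _fit_one(dfz, outcome)

    return MixedModelResult(
        outcome=outcome,
        fixed_effects=fe_raw,
        fixed_effects_std=fe_std,
        random_intercept_var=tau2,
        residual_var=sigma2,
        n_obs=int(df.shape[0]),
        n_participants=int(df["participant_id"].nunique()),
        converged=conv,
        boundary=tau2 < 1e-6 * max(sigma2, 1e-12),
    )
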