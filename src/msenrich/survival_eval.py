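"""Survival machinery and ranking-quality metrics.

Kaplan–Meier estimation (exponential-Greenwood confidence bands), restricted
mean survival time (RMST), the two-group log-rank test and univariate Cox
hazard ratios are delegated to lifelines. On top of these the module provides
the average-difference curve AD(c) — the ground-truth RMST difference between
arms among patients whose predicted effect exceeds the c-th percentile — and
its weighted area-between-curves summary AD_wabc, which score how well a CATE
estimator ranks patients by responsiveness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .exceptions import ParameterError, ValidationError

DEFAULT_AD_GRID = tuple(np.round(np.arange(0.0, 0.90, 0.05), 10))
DEFAULT_HORIZON = 2.0


@dataclass
class KMEstimate:
    """Product-limit survival estimate with 95% exponential-Greenwood CIs."""

    times: np.ndarray  # event-time grid (includes t=0)
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class ADCurve:
    """AD(c) values over percentile thresholds, with subset bookkeeping."""

    thresholds: np.ndarray  # fractions in [0, 1)
    values: np.ndarray  # RMST difference (years); NaN where undefined
    n_subset: np.ndarray
    n_treated: np.ndarray
    n_control: np.ndarray
    horizon: float = DEFAULT_HORIZON


@dataclass
class HazardRatioResult:
    hr: float
    ci_lower: float
    ci_upper: float
    p_logrank: float


def km_estimate(times, events, alpha: float = 0.05) -> KMEstimate:
    """Kaplan–Meier fit via lifelines (exponential-Greenwood CIs)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("km_estimate needs at least one observation")
    if np.all(times <= 0):
        raise ValidationError("all survival times are non-positive")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    ci = kmf.confidence_interval_
    table = kmf.event_table.reindex(grid)
    return KMEstimate(
        times=grid,
        survival=surv,
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        at_risk=table["at_risk"].to_numpy(dtype=float),
        events=table["observed"].to_numpy(dtype=float),
    )


def _km_step(times, events):
    """Vectorised KM point estimate: (unique event times, survival values)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, start = np.unique(t, return_index=True)
    counts = np.diff(np.append(start, t.size))
    d = np.add.reduceat(e.astype(float), start)  # events per unique time
    at_risk = t.size - start  # subjects with time >= uniq
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    keep = d > 0
    return uniq[keep], surv[keep]


def rmst(times, events, horizon: float = DEFAULT_HORIZON) -> float:
    """Area under the KM step function from 0 to ``horizon``.

    Survival is extended flat beyond the last observed time, so the RMST is
    always defined (and lies in [0, horizon]).
    """
    if horizon <= 0:
        raise ParameterError("horizon must be positive")
    et, surv = _km_step(times, events)
    area, prev_t, prev_s = 0.0, 0.0, 1.0
    for t, s in zip(et, surv):
        if t >= horizon:
            break
        area += prev_s * (t - prev_t)
        prev_t, prev_s = t, s
    area += prev_s * (horizon - prev_t)
    return float(area)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p-value."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValidationError("log-rank test undefined with no events in pooled data")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_hr(times, events, treated, alpha: float = 0.05) -> HazardRatioResult:
    """Univariate Cox PH fit on the treatment indicator.

    Returns the hazard ratio with a Wald CI; the reported p-value comes from
    the log-rank test, matching how trial publications pair the two.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    treated = np.asarray(treated, bool)
    if treated.all() or (~treated).all():
        raise ValidationError("both treatment-indicator levels must be present")
    df = pd.DataFrame({"time": times, "event": events.astype(int), "treated": treated.astype(int)})
    cph = CoxPHFitter(alpha=alpha)
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["treated"])
    se = float(cph.standard_errors_["treated"])
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    _, p = logrank_test(times[treated], events[treated], times[~treated], events[~treated])
    return HazardRatioResult(
        hr=float(np.exp(coef)),
        ci_lower=float(np.exp(coef - z * se)),
        ci_upper=float(np.exp(coef + z * se)),
        p_logrank=p,
    )


def ad_curve(
    cate_scores,
    times,
    events,
    treated,
    grid=None,
    horizon: float = DEFAULT_HORIZON,
) -> ADCurve:
    """Average-difference curve over percentile thresholds.

    For each threshold c the responder subset holds patients whose score is at
    least the empirical c-quantile (lower order statistic; threshold ties are
    all retained), and AD(c) is the treated-minus-control RMST difference at
    the horizon within that subset. AD(0) is the whole-group difference. A
    threshold where either arm is empty is recorded as NaN, not an error.
    """
    scores = np.asarray(cate_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    treated = np.asarray(treated, dtype=bool)
    if not (scores.size == times.size == events.size == treated.size):
        raise ValidationError("scores, labels and arms must align per patient")
    grid = np.asarray(DEFAULT_AD_GRID if grid is None else grid, dtype=float)
    if np.any(grid < 0) or np.any(grid >= 1) or np.any(np.diff(grid) <= 0):
        raise ParameterError("threshold grid must be strictly increasing within [0, 1)")

    values = np.full(grid.size, np.nan)
    n_sub = np.zeros(grid.size, dtype=int)
    n_trt = np.zeros(grid.size, dtype=int)
    n_ctl = np.zeros(grid.size, dtype=int)
    for k, c in enumerate(grid):
        thr = np.quantile(scores, c, method="lower")
        mask = scores >= thr
        n_sub[k] = int(mask.sum())
        trt, ctl = mask & treated, mask & ~treated
        n_trt[k], n_ctl[k] = int(trt.sum()), int(ctl.sum())
        if n_trt[k] == 0 or n_ctl[k] == 0:
            continue
        values[k] = rmst(times[trt], events[trt], horizon) - rmst(
            times[ctl], events[ctl], horizon
        )
    return ADCurve(grid, values, n_sub, n_trt, n_ctl, horizon)


def ad_wabc(curve: ADCurve, weighting: str = "retained") -> float:
    """Weighted area between AD(c) and its unenriched level AD(0).

    Trapezoidal integral of w(c)·[AD(c) − AD(0)] over the defined thresholds,
    normalised by the integral of w; w(c) = 1 − c (the retained cohort
    fraction) by default, or uniform. Larger positive values indicate a
    better responsiveness ranking.
    """
    defined = np.isfinite(curve.values)
    if not defined[0] or curve.thresholds[0] != 0.0:
        raise ValidationError("AD must be defined at c = 0")
    c = curve.thresholds[defined]
    if c.size < 2:
        raise ValidationError("need at least two defined thresholds")
    ad = curve.values[defined]
    if weighting == "retained":
        w = 1.0 - c
    elif weighting == "uniform":
        w = np.ones_like(c)
    else:
        raise ParameterError(f"unknown weighting {weighting!r}")
    num = np.trapezoid(w * (ad - ad[0]), c)
    den = np.trapezoid(w, c)
    return float(num / den)


def subgroup_stats(
    features: pd.DataFrame,
    responder_mask,
    binary_features: tuple[str, ...] = ("sex",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Responder vs non-responder characteristic table.

    Continuous/ordinal features: group means and SDs, mean-difference effect
    size with a Welch-Satterthwaite CI and a two-sided Welch t-test p-value.
    Binary features (sex): odds ratio with a Woolf CI and a two-sided Fisher
    exact p-value. Features with zero variance in both groups get p = 1 and a
    flag.
    """
    from scipy import stats as sps

    mask = np.asarray(responder_mask, dtype=bool)
    if mask.all() or (~mask).all():
        raise ValidationError("both responder groups must be non-empty")
    rows = []
    for name in features.columns:
        x = features.loc[mask, name].to_numpy(dtype=float)
        y = features.loc[~mask, name].to_numpy(dtype=float)
        if name in binary_features:
            a = int((x == 1).sum())
            b = int((x == 0).sum())
            c_ = int((y == 1).sum())
            d = int((y == 0).sum())
            oratio = (a * d) / (b * c_) if b * c_ > 0 else np.inf
            _, p = sps.fisher_exact([[a, b], [c_, d]], alternative="two-sided")
            if min(a, b, c_, d) > 0:
                se = np.sqrt(1 / a + 1 / b + 1 / c_ + 1 / d)
                z = sps.norm.ppf(1 - alpha / 2)
                lo, hi = np.exp(np.log(oratio) - z * se), np.exp(np.log(oratio) + z * se)
            else:
                lo = hi = np.nan
            rows.append(
                dict(feature=name, test="fisher", mean_resp=x.mean(), sd_resp=x.std(ddof=1),
                     mean_non=y.mean(), sd_non=y.std(ddof=1), effect=oratio,
                     ci_lower=lo, ci_upper=hi, p_value=float(p), degenerate=False)
            )
            continue
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        diff = x.mean() - y.mean()
        if vx == 0 and vy == 0:
            rows.append(
                dict(feature=name, test="welch", mean_resp=x.mean(), sd_resp=0.0,
                     mean_non=y.mean(), sd_non=0.0, effect=diff, ci_lower=diff,
                     ci_upper=diff, p_value=1.0, degenerate=True)
            )
            continue
        se = np.sqrt(vx / x.size + vy / y.size)
        dof = se**4 / ((vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1))
        _, p = sps.ttest_ind(x, y, equal_var=False)
        tcrit = sps.t.ppf(1 - alpha / 2, dof)
        rows.append(
            dict(feature=name, test="welch", mean_resp=x.mean(), sd_resp=x.std(ddof=1),
                 mean_non=y.mean(), sd_non=y.std(ddof=1), effect=diff,
                 ci_lower=diff - tcrit * se, ci_upper=diff + tcrit * se,
                 p_value=float(p), degenerate=False)
        )
    return pd.DataFrame(rows).set_index("feature")
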