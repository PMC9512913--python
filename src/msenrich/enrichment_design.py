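"""Enriched-trial design: log-rank sample sizes and the enrichment table.

Sample sizes for a two-sided log-rank comparison under a Cox proportional
hazards alternative follow Rosner's formulation: with allocation ratio
k (treatment:control), hazard ratio HR, and expected event probabilities
p_t, p_c,

    m = (1/k) * ((k*HR + 1)/(HR - 1))**2 * (z_{1-alpha/2} + z_{power})**2

events are needed in total, and the per-arm sample sizes are m*k/d and m/d
with d = k*p_t + p_c, each rounded up separately before summing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ParameterError, ValidationError
from .survival_eval import DEFAULT_HORIZON, cox_hr, _km_step


@dataclass
class EnrichmentRow:
    """One enrichment scenario: threshold, event rates, HR, sizes, screening."""

    percentile: float
    p_event_control: float
    p_event_treatment: float
    hr: float
    hr_ci_lower: float
    hr_ci_upper: float
    p_logrank: float
    n_treatment: int
    n_control: int
    n_total: int
    n_screened: int
    estimable: bool = True


def sample_size_cph(
    hr: float,
    p_event_treatment: float,
    p_event_control: float,
    ratio: float = 2.0,
    power: float = 0.8,
    alpha: float = 0.05,
) -> tuple[int, int, int]:
    """Per-arm and total sample size for a two-sided log-rank test.

    ``ratio`` is treatment:control participants (2.0 means 2:1). Each arm is
    rounded up to a whole participant before summing.
    """
    if hr <= 0:
        raise ParameterError("hazard ratio must be positive")
    if hr == 1:
        raise ParameterError("hazard ratio of 1 requires an infinite sample")
    for name, p in (("treatment", p_event_treatment), ("control", p_event_control)):
        if not 0 < p <= 1:
            raise ParameterError(f"{name} event rate must be in (0, 1]")
    if ratio <= 0:
        raise ParameterError("allocation ratio must be positive")
    k = float(ratio)
    z = norm.ppf(1 - alpha / 2) + norm.ppf(power)
    m = (1.0 / k) * ((k * hr + 1.0) / (hr - 1.0)) ** 2 * z**2
    d = k * p_event_treatment + p_event_control
    n_treatment = math.ceil(m * k / d)
    n_control = math.ceil(m / d)
    return n_treatment, n_control, n_treatment + n_control


def _event_rate(times, events, horizon: float, method: str = "km") -> float:
    """Probability of an event by ``horizon``: censoring-aware 1 - KM(horizon),
    or the crude observed proportion."""
    if method == "km":
        et, surv = _km_step(times, events)
        s = 1.0
        for t, sv in zip(et, surv):
            if t > horizon:
                break
            s = sv
        return 1.0 - float(s)
    if method == "crude":
        times = np.asarray(times, float)
        events = np.asarray(events, bool)
        return float(np.mean(events & (times <= horizon)))
    raise ParameterError(f"unknown event-rate method {method!r}")


def number_screened(n_total: int, percentile: float) -> int:
    """Participants screened so the top (100 - percentile)% fill the trial."""
    if not 0 <= percentile < 100:
        raise ParameterError("percentile must be in [0, 100)")
    return math.ceil(n_total / (1.0 - percentile / 100.0))


def enrichment_table(
    cate_scores,
    times,
    events,
    treated,
    percentiles=(0, 10, 20, 30, 40, 50, 60, 70),
    horizon: float = DEFAULT_HORIZON,
    ratio: float = 2.0,
    power: float = 0.8,
    alpha: float = 0.05,
    rate_method: str = "km",
) -> pd.DataFrame:
    """Per-percentile enrichment scenarios from observed trial data.

    For each percentile q, the responder subset holds patients with a score at
    or above the q-th percentile; its per-arm event rates at the horizon, Cox
    HR, required sample size at the given allocation ratio/power, and the
    number screened are tabulated. Subsets where the HR or sample size cannot
    be estimated are flagged rather than fatal.
    """
    scores = np.asarray(cate_scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    treated = np.asarray(treated, bool)
    if not (scores.size == times.size == events.size == treated.size):
        raise ValidationError("scores, labels and arms must align per patient")
    rows = []
    for q in percentiles:
        thr = np.quantile(scores, q / 100.0, method="lower")
        mask = scores >= thr
        trt, ctl = mask & treated, mask & ~treated
        row = EnrichmentRow(
            percentile=float(q), p_event_control=np.nan, p_event_treatment=np.nan,
            hr=np.nan, hr_ci_lower=np.nan, hr_ci_upper=np.nan, p_logrank=np.nan,
            n_treatment=0, n_control=0, n_total=0, n_screened=0, estimable=False,
        )
        if trt.sum() > 0 and ctl.sum() > 0 and events[trt].any() and events[ctl].any():
            row.p_event_treatment = _event_rate(times[trt], events[trt], horizon, rate_method)
            row.p_event_control = _event_rate(times[ctl], events[ctl], horizon, rate_method)
            try:
                res = cox_hr(times[mask], events[mask], treated[mask], alpha=alpha)
                row.hr, row.hr_ci_lower, row.hr_ci_upper = res.hr, res.ci_lower, res.ci_upper
                row.p_logrank = res.p_logrank
                if row.hr != 1 and 0 < row.p_event_treatment <= 1 and 0 < row.p_event_control <= 1:
                    nt, nc, ntot = sample_size_cph(
                        row.hr, row.p_event_treatment, row.p_event_control,
                        ratio=ratio, power=power, alpha=alpha,
                    )
                    row.n_treatment, row.n_control, row.n_total = nt, nc, ntot
                    row.n_screened = number_screened(ntot, q)
                    row.estimable = True
            except Exception:
                pass
        rows.append(row.__dict__)
    return pd.DataFrame(rows)
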