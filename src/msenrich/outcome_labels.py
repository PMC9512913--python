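"""Outcome labels: per-patient EDSS slope and time to 24-week confirmed
disability progression (CDP24).

The slope (EDSS change per year, ordinary least squares over all visits) is
the regression target used to train effect models; time-to-CDP24 is the
survival endpoint used for evaluation, matching standard progressive-MS trial
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .trial_data import Visit, WEEK_YEARS, is_valid_edss

CONFIRMATION_WEEKS = 24.0


@dataclass(frozen=True)
class SlopeLabel:
    patient_id: str
    slope: float  # EDSS units per year
    n_visits: int


@dataclass(frozen=True)
class SurvivalLabel:
    patient_id: str
    time: float  # years; onset time if event, last-visit time otherwise
    event: bool


def slope_label(visits: Sequence[Visit], patient_id: str = "") -> SlopeLabel:
    """OLS slope of EDSS on time (years) over all visits, baseline included."""
    if len(visits) < 2:
        raise ValidationError("slope label needs at least two visits")
    t = np.array([v.time for v in visits], dtype=float)
    y = np.array([v.edss for v in visits], dtype=float)
    if np.ptp(t) == 0:
        raise ValidationError("degenerate design: all visit times identical")
    tc = t - t.mean()
    slope = float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
    return SlopeLabel(patient_id=patient_id, slope=slope, n_visits=len(visits))


def progression_increment(baseline_edss: float) -> float:
    """EDSS increase required to qualify as progression, given baseline EDSS.

    1.5 points from a baseline of 0, 0.5 points above 5.5, 1.0 in between.
    """
    if not is_valid_edss(baseline_edss):
        raise ValidationError(f"baseline EDSS {baseline_edss} is off the valid grid")
    if baseline_edss == 0.0:
        return 1.5
    if baseline_edss > 5.5:
        return 0.5
    return 1.0


def cdp24_label(
    visits: Sequence[Visit],
    patient_id: str = "",
    confirmation_weeks: float = CONFIRMATION_WEEKS,
    strict: bool = True,
) -> SurvivalLabel:
    """Time-to-CDP24 with right censoring at the last visit.

    An onset visit qualifies if its EDSS reaches baseline + increment and the
    increase is sustained through the first visit at least ``confirmation_weeks``
    later. ``strict=True`` (default) requires every visit between onset and the
    confirming visit (inclusive) to stay at or above the threshold;
    ``strict=False`` checks the confirming visit only. Event time is the onset
    visit time.
    """
    if len(visits) < 2:
        raise ValidationError("CDP24 label needs at least two visits")
    t = np.array([v.time for v in visits], dtype=float)
    y = np.array([v.edss for v in visits], dtype=float)
    if t[0] != 0.0:
        raise ValidationError("first visit must be the baseline (time 0)")
    threshold = y[0] + progression_increment(y[0])
    window = confirmation_weeks * WEEK_YEARS
    n = len(visits)
    for i in range(1, n):
        if y[i] < threshold:
            continue
        # first visit at least `window` after the candidate onset
        later = np.nonzero(t >= t[i] + window - 1e-9)[0]
        if later.size == 0:
            continue  # no confirming visit exists
        j = int(later[0])
        span = slice(i + 1, j + 1) if strict else slice(j, j + 1)
        if np.all(y[span] >= threshold):
            return SurvivalLabel(patient_id=patient_id, time=float(t[i]), event=True)
    return SurvivalLabel(patient_id=patient_id, time=float(t[-1]), event=False)


def label_dataset(dataset, strict: bool = True):
    """Convenience: slope + CDP24 labels for every patient as a DataFrame."""
    import pandas as pd

    rows = []
    for p in dataset.patients:
        s = slope_label(p.visits, p.patient_id)
        c = cdp24_label(p.visits, p.patient_id, strict=strict)
        rows.append(
            {
                "patient_id": p.patient_id,
                "slope": s.slope,
                "n_visits": s.n_visits,
                "ttcdp24_years": c.time,
                "event": c.event,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
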