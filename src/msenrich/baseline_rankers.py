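"""Comparator CATE rankers: single-feature rules, feature/disease-duration
ratios, ridge and Cox proportional-hazards T-learners, a prognostic model,
and the age<51 & Gad>0 binary rule.

All rankers emit one score per patient; only the induced ordering matters to
the AD(c)/AD_wabc evaluation, so scores on different scales are comparable
through it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.linear_model import Ridge

from .exceptions import ParameterError, ValidationError
from .cate_mlp import EnsembleModel, HyperParams, cross_validated_ensemble


def feature_ranker(
    features: pd.DataFrame,
    feature: str,
    sign: int = 1,
    divide_by_disease_duration: bool = False,
) -> np.ndarray:
    """sign * feature (optionally / disease duration) as the CATE estimate.

    "Negative disease duration" (sign=-1 on disease_duration) ranks shorter
    disease duration as more responsive; the ratio form reads as a historical
    rate of change of the feature since symptom onset.
    """
    if sign not in (1, -1):
        raise ParameterError("sign must be +1 or -1")
    if feature not in features.columns:
        raise ValidationError(f"feature {feature!r} not present")
    values = features[feature].to_numpy(dtype=float)
    if divide_by_disease_duration:
        dur = features["disease_duration"].to_numpy(dtype=float)
        zero = np.nonzero(dur == 0)[0]
        if zero.size:
            ids = list(features.index[zero])
            raise ValidationError(f"zero disease duration for patients {ids}")
        values = values / dur
    return sign * values


@dataclass
class RidgeTLearner:
    """One L2-regularized linear slope regression per arm; CATE is the
    sign-flipped difference -(mu_treatment - mu_control)."""

    alpha: float = 1.0
    model_treatment: Ridge | None = None
    model_control: Ridge | None = None

    def fit(self, X, y, treated) -> "RidgeTLearner":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        treated = np.asarray(treated, bool)
        if treated.all() or (~treated).all():
            raise ValidationError("both arms must be present to fit a T-learner")
        self.model_treatment = Ridge(alpha=self.alpha).fit(X[treated], y[treated])
        self.model_control = Ridge(alpha=self.alpha).fit(X[~treated], y[~treated])
        return self

    def predict_cate(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        return -(self.model_treatment.predict(X) - self.model_control.predict(X))


@dataclass
class CoxTLearner:
    """One Cox PH time-to-CDP24 model per arm (Breslow ties).

    The CATE score is the control-arm linear predictor minus the
    treatment-arm linear predictor: higher means a larger predicted reduction
    in progression risk on treatment. Only the ordering is consumed
    downstream.
    """

    penalizer: float = 0.1
    model_treatment: CoxPHFitter | None = None
    model_control: CoxPHFitter | None = None
    _columns: list | None = None

    def fit(self, X, times, events, treated) -> "CoxTLearner":
        Xdf = pd.DataFrame(np.asarray(X, float))
        self._columns = list(Xdf.columns)
        times = np.asarray(times, float)
        events = np.asarray(events, bool)
        treated = np.asarray(treated, bool)
        if treated.all() or (~treated).all():
            raise ValidationError("both arms must be present to fit a T-learner")
        for is_trt in (True, False):
            rows = treated if is_trt else ~treated
            df = Xdf.loc[rows].copy()
            df["time"], df["event"] = times[rows], events[rows].astype(int)
            cph = CoxPHFitter(penalizer=self.penalizer)
            cph.fit(df, duration_col="time", event_col="event")
            if is_trt:
                self.model_treatment = cph
            else:
                self.model_control = cph
        return self

    def _linear_predictor(self, model: CoxPHFitter, X) -> np.ndarray:
        df = pd.DataFrame(np.asarray(X, float), columns=self._columns)
        return model.predict_log_partial_hazard(df).to_numpy()

    def predict_cate(self, X) -> np.ndarray:
        return self._linear_predictor(self.model_control, X) - self._linear_predictor(
            self.model_treatment, X
        )


def tlearner_fit(X, labels, treated, base: str = "ridge", hp: dict | None = None):
    """Fit a T-learner ranker.

    ``base="ridge"`` expects ``labels`` to be slope targets; ``base="cph"``
    expects ``labels = (times, events)`` for CDP24.
    """
    hp = hp or {}
    if base == "ridge":
        return RidgeTLearner(alpha=hp.get("alpha", 1.0)).fit(X, labels, treated)
    if base == "cph":
        times, events = labels
        return CoxTLearner(penalizer=hp.get("penalizer", 0.1)).fit(X, times, events, treated)
    raise ParameterError(f"unknown T-learner base {base!r}")


@dataclass
class PrognosticRanker:
    """Placebo-only slope model; the predicted untreated slope is the score
    (faster predicted worsening ranks as more responsive)."""

    ensemble: EnsembleModel

    def predict_score(self, X) -> np.ndarray:
        return self.ensemble.predict(X)[:, 0]


def prognostic_ranker(
    X_placebo, y_placebo, hp: HyperParams | None = None, k: int = 4
) -> PrognosticRanker:
    """Train the MLP machinery on placebo patients only (single head)."""
    X_placebo = np.asarray(X_placebo, float)
    if X_placebo.shape[0] == 0:
        raise ValidationError("no placebo patients to train the prognostic model on")
    hp = hp or HyperParams()
    alloc = np.array(["placebo"] * X_placebo.shape[0])
    ensemble, _ = cross_validated_ensemble(
        X_placebo, y_placebo, alloc, hp, k=k, arm_ids=("placebo",)
    )
    return PrognosticRanker(ensemble=ensemble)


def hawker_rule(features: pd.DataFrame) -> np.ndarray:
    """Responder iff age < 51 years and Gad lesion count > 0 (raw features)."""
    age = features["age"].to_numpy(dtype=float)
    gad = features["gad_count"].to_numpy(dtype=float)
    return (age < 51.0) & (gad > 0.0)
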