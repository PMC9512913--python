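"""Synthetic randomized-trial generator with known ground-truth treatment
effects.

Emulates the structure of pooled progressive-MS trial data: multi-trial,
multi-arm randomization (2:1-capable), baseline features with realistic
progressive-MS means/SDs, longitudinal EDSS trajectories on the valid grid
driven by a latent per-patient slope, a heterogeneous feature-dependent
treatment effect on that slope, scheduled visits with exponential dropout,
and inter-trial scale shifts in the segmentation-derived MRI metrics.

The generator defines the study conditions for every test in the package:
a positive true effect tau(x) means slower worsening on treatment
(benefit-positive convention, matching the sign-flipped CATE reported by the
effect models).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .trial_data import (
    PatientRecord,
    TrialDataset,
    Visit,
    WEEK_YEARS,
    default_schema,
    snap_to_edss_grid,
)

# anchor constants used by the default slope/effect functions so that they are
# deterministic functions of the raw features (approximate PPMS-cohort scales)
_AGE_ANCHOR = (46.0, 8.0)
_EDSS_ANCHOR = (4.6, 1.2)
_LOGT2_ANCHOR = (1.9, 0.9)  # ln(T2 volume + 1)


@dataclass(frozen=True)
class TrialConfig:
    """One synthetic trial: size, arms, allocation weights, MRI scale shift."""

    trial_id: str
    n: int
    arm_ids: tuple[str, ...]
    allocation: tuple[float, ...]  # relative randomization weights, e.g. (2, 1)
    mri_shift: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    # feature -> (multiplier, offset) applied to the sampled value

    def __post_init__(self):
        if self.n <= 0:
            raise ParameterError("trial n must be positive")
        if len(self.allocation) != len(self.arm_ids):
            raise ParameterError("allocation weights must match arm_ids")


@dataclass
class SyntheticConfig:
    """Full generator configuration; defaults emulate a PPMS-like cohort."""

    trials: tuple[TrialConfig, ...]
    arms: dict[str, dict]
    placebo_slope: Callable[[pd.DataFrame], np.ndarray] | None = None
    cate: Callable[[pd.DataFrame], np.ndarray] | None = None
    arm_effect: Mapping[str, float] | None = None  # multiplier on tau per arm
    visit_schedule_weeks: tuple[float, ...] = tuple(range(0, 121, 12))
    edss_noise_sd: float = 0.3
    slope_noise_sd: float = 0.4
    dropout_hazard: float = 0.08  # per year, arm-independent
    seed: int = 0

    def __post_init__(self):
        if self.edss_noise_sd < 0 or self.slope_noise_sd < 0:
            raise ParameterError("noise SDs must be non-negative")
        if not self.visit_schedule_weeks or self.visit_schedule_weeks[0] != 0:
            raise ParameterError("visit schedule must start at week 0")
        if any(
            b <= a
            for a, b in zip(self.visit_schedule_weeks, self.visit_schedule_weeks[1:])
        ):
            raise ParameterError("visit schedule must be strictly increasing")


def _unbiased_grid_round(value: float, u: float) -> float:
    """Stochastic rounding of a continuous disability level to the EDSS grid.

    The value is rounded to one of its two neighbouring grid points with
    probabilities proportional to proximity, so the observed score is an
    unbiased quantization of the latent level (a deterministic
    nearest-rounding of a slowly drifting trajectory would bias fitted
    slopes). ``u`` is a uniform(0,1) draw.
    """
    v = min(max(value, 0.0), 10.0)
    if v < 1.0:  # the grid has no 0.5 step between 0 and 1
        lower, upper = 0.0, 1.0
    else:
        lower = np.floor(v * 2.0) / 2.0
        upper = min(lower + 0.5, 10.0)
    if upper == lower:
        return lower
    frac = (v - lower) / (upper - lower)
    return upper if u < frac else lower


def default_placebo_slope(features: pd.DataFrame) -> np.ndarray:
    """Mean untreated EDSS slope (~0.25/yr), worse with higher baseline EDSS
    and lesion load — loosely matching observed PPMS placebo-arm slopes."""
    z_edss = (features["edss"].to_numpy() - _EDSS_ANCHOR[0]) / _EDSS_ANCHOR[1]
    z_t2 = (
        np.log(features["t2_lesion_volume"].to_numpy() + 1.0) - _LOGT2_ANCHOR[0]
    ) / _LOGT2_ANCHOR[1]
    return 0.25 + 0.08 * z_edss + 0.05 * z_t2


def linear_cate(strength: float = 1.0) -> Callable[[pd.DataFrame], np.ndarray]:
    """A linear, feature-dependent true effect on the slope scale.

    Larger with more lesion activity, younger age and higher baseline EDSS;
    at strength 1 the effect has mean ~0.12 and SD ~0.14 EDSS/yr.
    """

    def tau(features: pd.DataFrame) -> np.ndarray:
        z_t2 = (
            np.log(features["t2_lesion_volume"].to_numpy() + 1.0) - _LOGT2_ANCHOR[0]
        ) / _LOGT2_ANCHOR[1]
        z_age = (_AGE_ANCHOR[0] - features["age"].to_numpy()) / _AGE_ANCHOR[1]
        z_edss = (features["edss"].to_numpy() - _EDSS_ANCHOR[0]) / _EDSS_ANCHOR[1]
        return strength * (0.12 + 0.10 * z_t2 + 0.08 * z_age + 0.05 * z_edss)

    return tau


def strong_linear_cate() -> Callable[[pd.DataFrame], np.ndarray]:
    """Strong linear effect heterogeneity (SD ~0.2 EDSS/yr) used by the
    recovery and ranking-metric study conditions."""
    return linear_cate(1.5)


def constant_cate(value: float) -> Callable[[pd.DataFrame], np.ndarray]:
    return lambda features: np.full(len(features), float(value))


def ppms_config(
    n: int = 2000,
    cate: Callable[[pd.DataFrame], np.ndarray] | None = None,
    seed: int = 0,
    n_trials: int = 2,
    allocation: tuple[float, float] = (2.0, 1.0),
    **overrides,
) -> SyntheticConfig:
    """Two-arm (treatment vs placebo) PPMS-like configuration, optionally
    split across ``n_trials`` trials with mild MRI scale shifts."""
    per = [n // n_trials] * n_trials
    per[0] += n - sum(per)
    shifts = [
        {} if i == 0 else {"t2_lesion_volume": (1.0 + 0.1 * i, 0.0), "gad_count": (1.0, 0.0)}
        for i in range(n_trials)
    ]
    trials = tuple(
        TrialConfig(
            trial_id=f"TRIAL_{chr(65 + i)}",
            n=per[i],
            arm_ids=("treatment", "placebo"),
            allocation=allocation,
            mri_shift=shifts[i],
        )
        for i in range(n_trials)
    )
    arms = {
        "treatment": {"name": "active", "is_control": False},
        "placebo": {"name": "placebo", "is_control": True},
    }
    return SyntheticConfig(trials=trials, arms=arms, cate=cate, seed=seed, **overrides)


def rrms_config(
    n: int = 2500,
    cate: Callable[[pd.DataFrame], np.ndarray] | None = None,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """Five-arm RRMS-like configuration for the pre-training phase (four
    active arms plus placebo, milder mean progression)."""
    arm_ids = ("anti_cd20", "sc_ifnb1a", "laquinimod", "im_ifnb1a", "placebo")
    trials = (
        TrialConfig(
            trial_id="RRMS_A",
            n=n,
            arm_ids=arm_ids,
            allocation=(1.0, 1.0, 1.0, 1.0, 1.0),
        ),
    )
    arms = {a: {"name": a, "is_control": a == "placebo"} for a in arm_ids}
    # distinct per-arm responsiveness so the trunk sees arm-dependent structure
    arm_effect = {
        "anti_cd20": 1.0,
        "sc_ifnb1a": 0.6,
        "laquinimod": 0.4,
        "im_ifnb1a": 0.5,
        "placebo": 0.0,
    }
    cfg = SyntheticConfig(
        trials=trials,
        arms=arms,
        cate=cate,
        arm_effect=arm_effect,
        placebo_slope=lambda f: 0.6 * default_placebo_slope(f),
        seed=seed,
        **overrides,
    )
    return cfg


def true_cate(config: SyntheticConfig, features: pd.DataFrame) -> np.ndarray:
    """Ground-truth tau(x) on the benefit-positive slope scale."""
    if config.cate is None:
        return np.zeros(len(features))
    return np.asarray(config.cate(features), dtype=float)


def _sample_features(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Baseline feature draws roughly matching PPMS trial-arm summaries."""
    fss_means = {
        "fss_bowel_bladder": 1.2,
        "fss_brainstem": 0.85,
        "fss_cerebellar": 2.1,
        "fss_cerebral": 1.0,
        "fss_pyramidal": 2.8,
        "fss_sensory": 1.6,
        "fss_visual": 0.8,
    }
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(46.0, 8.0, n), 18.0, 65.0),
            "sex": rng.integers(0, 2, n).astype(float),
            "height": rng.normal(170.0, 9.5, n),
            "weight": np.clip(rng.normal(74.0, 16.0, n), 35.0, 160.0),
            "disease_duration": np.clip(rng.lognormal(1.8, 0.6, n), 0.25, 40.0),
            "edss": [
                snap_to_edss_grid(v) for v in np.clip(rng.normal(4.6, 1.2, n), 1.0, 6.5)
            ],
            "t25fw": np.clip(rng.lognormal(2.3, 0.5, n), 2.0, 180.0),
            "nhpt_dominant": np.clip(rng.lognormal(3.3, 0.35, n), 10.0, 300.0),
            "nhpt_nondominant": np.clip(rng.lognormal(3.4, 0.35, n), 10.0, 300.0),
            "gad_count": np.where(
                rng.random(n) < 0.65, 0.0, rng.poisson(1.6, n).astype(float)
            ),
            "t2_lesion_volume": np.clip(rng.lognormal(1.8, 1.0, n), 0.0, 120.0),
            "nbv": np.clip(rng.normal(1.45, 0.09, n), 1.1, 1.75),
        }
    )
    for name, mean in fss_means.items():
        df[name] = np.clip(np.round(rng.normal(mean, 0.9, n)), 0, 6).astype(float)
    return df[list(default_schema().names)]


def generate_dataset(config: SyntheticConfig) -> tuple[TrialDataset, pd.DataFrame]:
    """Generate a full synthetic dataset plus its ground-truth table.

    Returns the :class:`TrialDataset` (patients with scheduled, possibly
    censored EDSS visit series) and a DataFrame with one row per patient:
    true tau(x) (benefit-positive), the latent slope actually used, arm and
    trial ids.
    """
    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    truth_rows = []
    schedule_years = np.array(config.visit_schedule_weeks, dtype=float) * WEEK_YEARS
    arm_effect = config.arm_effect or {
        a: (0.0 if meta.get("is_control") else 1.0) for a, meta in config.arms.items()
    }
    slope_fn = config.placebo_slope or default_placebo_slope

    for trial in config.trials:
        feats = _sample_features(rng, trial.n)
        for feat, (mult, off) in trial.mri_shift.items():
            feats[feat] = feats[feat] * mult + off
        probs = np.array(trial.allocation, dtype=float)
        probs /= probs.sum()
        arm_idx = rng.choice(len(trial.arm_ids), size=trial.n, p=probs)
        arms = np.array(trial.arm_ids)[arm_idx]

        tau = true_cate(config, feats)
        beta0 = np.asarray(slope_fn(feats), dtype=float)
        eff = np.array([arm_effect[a] for a in arms])
        latent = beta0 - tau * eff + rng.normal(0.0, config.slope_noise_sd, trial.n)

        if config.dropout_hazard > 0:
            censor = rng.exponential(1.0 / config.dropout_hazard, trial.n)
        else:
            censor = np.full(trial.n, np.inf)
        noise = rng.normal(0.0, config.edss_noise_sd, (trial.n, len(schedule_years)))
        dither = rng.random((trial.n, len(schedule_years)))

        for i in range(trial.n):
            pid = f"{trial.trial_id}-{i:05d}"
            base = feats.at[i, "edss"]
            visits = [Visit(0.0, base)]
            for k, t in enumerate(schedule_years[1:], start=1):
                if t > censor[i]:
                    break
                value = _unbiased_grid_round(
                    base + latent[i] * t + noise[i, k], dither[i, k]
                )
                visits.append(Visit(float(t), value))
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    trial_id=trial.trial_id,
                    arm_id=str(arms[i]),
                    features={k: float(v) for k, v in feats.iloc[i].items()},
                    visits=visits,
                )
            )
            truth_rows.append(
                {
                    "patient_id": pid,
                    "true_cate": float(tau[i]),
                    "latent_slope": float(latent[i]),
                    "trial_id": trial.trial_id,
                    "arm_id": str(arms[i]),
                }
            )

    trials_meta = {t.trial_id: {"n": t.n} for t in config.trials}
    dataset = TrialDataset(patients, dict(config.arms), trials_meta)
    truth = pd.DataFrame(truth_rows).set_index("patient_id")
    return dataset, truth
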