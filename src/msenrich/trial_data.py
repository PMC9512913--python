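"""Data model and preprocessing for pooled multi-trial MS progression data.

One baseline row per randomized participant (19 clinical/MRI features) plus a
long-format visit table of EDSS scores over time. Preprocessing follows the
order: cross-trial rescaling of segmentation-derived MRI metrics toward a
reference trial, natural-log transform of right-skewed features, ordinal
binning of gadolinium-enhancing lesion counts, and z-standardization of all
non-binary features with statistics fitted on the training split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ParameterError,
    SchemaError,
    StandardizationError,
    ValidationError,
)

WEEK_YEARS = 7.0 / 365.25
#: minimum in-trial time for inclusion (24 weeks, in years)
MIN_FOLLOWUP_YEARS = 24.0 * WEEK_YEARS

#: Gad-count bin lower edges: 0, 1, 2, 3, 4, 5-6, 7-9, 10-14, 15-19, 20+
GAD_BIN_EDGES = (1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 20.0)


def is_valid_edss(value: float) -> bool:
    """EDSS lives on 0.0, 1.0, 1.5, ..., 10.0 — half points, but no 0.5."""
    if not np.isfinite(value) or value < 0.0 or value > 10.0:
        return False
    doubled = value * 2.0
    if abs(doubled - round(doubled)) > 1e-9:
        return False
    return abs(value - 0.5) > 1e-9


def snap_to_edss_grid(value: float) -> float:
    """Round an arbitrary score to the nearest valid EDSS grid point."""
    v = min(max(value, 0.0), 10.0)
    v = round(v * 2.0) / 2.0
    if abs(v - 0.5) < 1e-9:
        # no 0.5 step between 0 and 1: snap to the nearer endpoint
        v = 1.0 if value >= 0.5 else 0.0
    return v


@dataclass(frozen=True)
class Visit:
    """A single clinical visit: time from baseline (years) and EDSS."""

    time: float
    edss: float

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"visit time must be finite and >= 0, got {self.time}")
        if not is_valid_edss(self.edss):
            raise ValidationError(
                f"EDSS {self.edss} is off the valid grid "
                "(0.0 or 1.0..10.0 in 0.5 steps; 0.5 itself is invalid)"
            )


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str  # binary | ordinal | discrete | continuous
    log_transform: bool = False
    mri_scaled: bool = False


@dataclass(frozen=True)
class FeatureSchema:
    """Names, kinds and preprocessing flags for the baseline feature vector."""

    features: tuple[FeatureSpec, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise SchemaError(f"unknown feature {name!r}")

    def names_where(self, predicate: Callable[[FeatureSpec], bool]) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if predicate(f))


def default_schema() -> FeatureSchema:
    """The 19-feature baseline schema used throughout.

    Log transform is applied to the right-skewed timed tests and volumetrics
    (T25FW, both 9HPT hands, T2 lesion volume, NBV); cross-trial rescaling to
    the segmentation-derived MRI metrics (Gad count, T2 volume, NBV).
    """
    f = FeatureSpec
    return FeatureSchema(
        (
            f("age", "continuous"),
            f("sex", "binary"),
            f("height", "continuous"),
            f("weight", "continuous"),
            f("disease_duration", "continuous"),
            f("edss", "ordinal"),
            f("fss_bowel_bladder", "ordinal"),
            f("fss_brainstem", "ordinal"),
            f("fss_cerebellar", "ordinal"),
            f("fss_cerebral", "ordinal"),
            f("fss_pyramidal", "ordinal"),
            f("fss_sensory", "ordinal"),
            f("fss_visual", "ordinal"),
            f("t25fw", "continuous", log_transform=True),
            f("nhpt_dominant", "continuous", log_transform=True),
            f("nhpt_nondominant", "continuous", log_transform=True),
            f("gad_count", "discrete", mri_scaled=True),
            f("t2_lesion_volume", "continuous", log_transform=True, mri_scaled=True),
            f("nbv", "continuous", log_transform=True, mri_scaled=True),
        )
    )


@dataclass
class PatientRecord:
    """Baseline features plus the longitudinal EDSS series of one participant."""

    patient_id: str
    trial_id: str
    arm_id: str
    features: dict[str, float]
    visits: list[Visit] = field(default_factory=list)

    def validate(self, schema: FeatureSchema) -> None:
        missing = set(schema.names) - set(self.features)
        extra = set(self.features) - set(schema.names)
        if missing or extra:
            raise SchemaError(
                f"patient {self.patient_id}: feature map mismatch "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        times = [v.time for v in self.visits]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"patient {self.patient_id}: visits not strictly time-ordered")

    @property
    def last_visit_time(self) -> float:
        return self.visits[-1].time if self.visits else 0.0


@dataclass
class TrialDataset:
    """Patients plus arm/trial registries for a pooled multi-trial cohort."""

    patients: list[PatientRecord]
    arms: dict[str, dict]
    trials: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen:
                raise ValidationError(f"duplicate patient_id {p.patient_id!r}")
            seen.add(p.patient_id)
            if p.arm_id not in self.arms:
                raise ValidationError(
                    f"patient {p.patient_id}: arm_id {p.arm_id!r} not in arm registry"
                )
            if self.trials and p.trial_id not in self.trials:
                raise ValidationError(
                    f"patient {p.patient_id}: trial_id {p.trial_id!r} not in trial registry"
                )

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def subset(self, patient_ids: Iterable[str]) -> "TrialDataset":
        wanted = set(patient_ids)
        return TrialDataset(
            patients=[p for p in self.patients if p.patient_id in wanted],
            arms=self.arms,
            trials=self.trials,
        )

    def baseline_frame(self, schema: FeatureSchema | None = None) -> pd.DataFrame:
        """Raw baseline features as a DataFrame indexed by patient_id."""
        schema = schema or default_schema()
        rows = {p.patient_id: {**p.features} for p in self.patients}
        df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=schema.names)
        df.insert(0, "trial_id", [p.trial_id for p in self.patients])
        df.insert(1, "arm_id", [p.arm_id for p in self.patients])
        df.index.name = "patient_id"
        return df

    def control_arm_ids(self) -> list[str]:
        return [a for a, meta in self.arms.items() if meta.get("is_control")]


def load_trial_table(
    baseline_path: str | Path,
    visits_path: str | Path,
    arm_registry: Mapping[str, dict],
    trial_registry: Mapping[str, dict] | None = None,
    schema: FeatureSchema | None = None,
) -> TrialDataset:
    """Read the baseline and visit CSVs into a validated :class:`TrialDataset`.

    ``patients.csv`` needs columns patient_id, trial_id, arm_id plus the 19
    schema features; ``visits.csv`` is long format (patient_id, time_years,
    edss). Visits are attached sorted by time; visit rows referencing unknown
    patients are rejected.
    """
    schema = schema or default_schema()
    baseline = pd.read_csv(baseline_path, dtype={"patient_id": str})
    visits = pd.read_csv(visits_path, dtype={"patient_id": str})

    required = ["patient_id", "trial_id", "arm_id", *schema.names]
    for col in required:
        if col not in baseline.columns:
            raise SchemaError(f"baseline table is missing column {col!r}")
    for col in ("patient_id", "time_years", "edss"):
        if col not in visits.columns:
            raise SchemaError(f"visits table is missing column {col!r}")

    known = set(baseline["patient_id"])
    unknown = sorted(set(visits["patient_id"]) - known)
    if unknown:
        raise ValidationError(f"visits reference unknown patient_ids: {unknown}")

    for idx, row in visits.iterrows():
        if not is_valid_edss(float(row["edss"])):
            raise ValidationError(
                f"visits row {idx}: EDSS {row['edss']} is off the valid grid"
            )

    by_patient: dict[str, list[Visit]] = {}
    for pid, grp in visits.groupby("patient_id", sort=False):
        grp = grp.sort_values("time_years")
        by_patient[pid] = [
            Visit(float(t), float(e)) for t, e in zip(grp["time_years"], grp["edss"])
        ]

    patients = []
    for _, row in baseline.iterrows():
        feats = {}
        for name in schema.names:
            val = row[name]
            feats[name] = float(val) if pd.notna(val) else float("nan")
        rec = PatientRecord(
            patient_id=str(row["patient_id"]),
            trial_id=str(row["trial_id"]),
            arm_id=str(row["arm_id"]),
            features=feats,
            visits=by_patient.get(str(row["patient_id"]), []),
        )
        rec.validate(schema)
        patients.append(rec)
    return TrialDataset(patients, dict(arm_registry), dict(trial_registry or {}))


def apply_exclusions(
    dataset: TrialDataset,
    min_followup_years: float = MIN_FOLLOWUP_YEARS,
    schema: FeatureSchema | None = None,
) -> tuple[TrialDataset, list[tuple[str, str]]]:
    """Drop participants per the cohort rules; return (dataset, exclusion log).

    Rules: fewer than two clinical visits; last visit earlier than 24 weeks;
    any missing baseline feature. The first matching rule is logged.
    """
    schema = schema or default_schema()
    kept, log = [], []
    for p in dataset.patients:
        if len(p.visits) < 2:
            log.append((p.patient_id, "fewer than two clinical visits"))
        elif p.last_visit_time < min_followup_years:
            log.append((p.patient_id, "less than 24 weeks in the trial"))
        elif any(not np.isfinite(p.features.get(n, float("nan"))) for n in schema.names):
            log.append((p.patient_id, "missing baseline feature"))
        else:
            kept.append(p)
    return TrialDataset(kept, dataset.arms, dataset.trials), log


def scale_to_reference(value, source_mean, source_sd, ref_mean, ref_sd):
    """Map a value so the source ±3 SD range coincides with the reference one.

    The value is first clamped to the source mean ±3 SD (robustness to extreme
    outliers), then linearly mapped z-for-z onto the reference scale. Accepts
    scalars or arrays.
    """
    if source_sd <= 0 or ref_sd <= 0:
        raise ParameterError("standard deviations must be positive for cross-trial scaling")
    lo, hi = source_mean - 3.0 * source_sd, source_mean + 3.0 * source_sd
    clamped = np.clip(value, lo, hi)
    z = (clamped - source_mean) / source_sd
    out = ref_mean + z * ref_sd
    return float(out) if np.isscalar(value) else out


def gad_bin(count) -> np.ndarray:
    """Ordinal code 0..9 for a Gad lesion count (bins 0,1,2,3,4,5-6,7-9,10-14,15-19,20+)."""
    return np.digitize(np.asarray(count, dtype=float), GAD_BIN_EDGES)


@dataclass
class FittedPreprocessor:
    """Frozen preprocessing state: MRI scaling anchors, log offset, Gad bins,
    and per-feature standardization statistics (training split only)."""

    schema: FeatureSchema
    reference_trial_id: str
    mri_anchors: dict[str, dict[str, tuple[float, float]]]  # trial -> feature -> (mean, sd)
    ref_anchors: dict[str, tuple[float, float]]  # feature -> (mean, sd)
    standardize_stats: dict[str, tuple[float, float]]  # feature -> (mean, sd)
    log_eps: float = 0.01
    gad_bin_edges: tuple[float, ...] = GAD_BIN_EDGES

    def transform_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Apply the fitted pipeline to a raw baseline frame (needs trial_id)."""
        df = frame.copy()
        mri_feats = self.schema.names_where(lambda f: f.mri_scaled)
        for feat in mri_feats:
            ref_mean, ref_sd = self.ref_anchors[feat]
            col = df[feat].astype(float).to_numpy()
            out = np.empty_like(col)
            for trial, idx in df.groupby("trial_id").groups.items():
                if trial not in self.mri_anchors:
                    raise ValidationError(f"trial {trial!r} has no fitted MRI anchors")
                mean, sd = self.mri_anchors[trial][feat]
                pos = df.index.get_indexer(idx)
                out[pos] = scale_to_reference(col[pos], mean, sd, ref_mean, ref_sd)
            df[feat] = out
        for feat in self.schema.names_where(lambda f: f.log_transform):
            # floor at 0 first: cross-trial rescaling can push a small MRI
            # value slightly negative, and the offset must keep the log finite
            df[feat] = np.log(np.maximum(df[feat].astype(float), 0.0) + self.log_eps)
        df["gad_count"] = np.digitize(
            df["gad_count"].astype(float).to_numpy(), self.gad_bin_edges
        ).astype(float)
        for feat in self.schema.names:
            if self.schema[feat].kind == "binary":
                continue
            mean, sd = self.standardize_stats[feat]
            df[feat] = (df[feat].astype(float) - mean) / sd
        return df[list(self.schema.names)].astype(float)

    def transform(self, dataset: TrialDataset) -> pd.DataFrame:
        return self.transform_frame(dataset.baseline_frame(self.schema))

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "reference_trial_id": self.reference_trial_id,
            "log_eps": self.log_eps,
            "gad_bin_edges": list(self.gad_bin_edges),
            "mri_anchors": {
                t: {f: list(v) for f, v in feats.items()}
                for t, feats in self.mri_anchors.items()
            },
            "ref_anchors": {f: list(v) for f, v in self.ref_anchors.items()},
            "standardize_stats": {f: list(v) for f, v in self.standardize_stats.items()},
            "schema": [
                [f.name, f.kind, f.log_transform, f.mri_scaled]
                for f in self.schema.features
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedPreprocessor":
        d = json.loads(text)
        schema = FeatureSchema(
            tuple(FeatureSpec(n, k, bool(lg), bool(mr)) for n, k, lg, mr in d["schema"])
        )
        return cls(
            schema=schema,
            reference_trial_id=d["reference_trial_id"],
            mri_anchors={
                t: {f: tuple(v) for f, v in feats.items()}
                for t, feats in d["mri_anchors"].items()
            },
            ref_anchors={f: tuple(v) for f, v in d["ref_anchors"].items()},
            standardize_stats={f: tuple(v) for f, v in d["standardize_stats"].items()},
            log_eps=float(d["log_eps"]),
            gad_bin_edges=tuple(d["gad_bin_edges"]),
        )


def fit_preprocessor(
    dataset: TrialDataset,
    schema: FeatureSchema | None = None,
    reference_trial_id: str | None = None,
    training_ids: Sequence[str] | None = None,
    log_eps: float = 0.01,
    inclusion: Callable[[pd.Series], bool] | None = None,
) -> FittedPreprocessor:
    """Fit all preprocessing statistics on the training split.

    ``inclusion`` optionally restricts the rows used to fit the MRI scaling
    anchors (the cross-trial intersection-of-inclusion-criteria subset);
    the default uses every training row.
    """
    schema = schema or default_schema()
    frame = dataset.baseline_frame(schema)
    train = frame.loc[list(training_ids)] if training_ids is not None else frame
    if reference_trial_id is None:
        reference_trial_id = train["trial_id"].mode().iloc[0]
    if reference_trial_id not in set(train["trial_id"]):
        raise ValidationError(f"reference trial {reference_trial_id!r} absent from training split")

    anchor_rows = train
    if inclusion is not None:
        mask = train.apply(inclusion, axis=1).astype(bool)
        anchor_rows = train.loc[mask]

    mri_feats = schema.names_where(lambda f: f.mri_scaled)
    mri_anchors: dict[str, dict[str, tuple[float, float]]] = {}
    for trial, grp in anchor_rows.groupby("trial_id"):
        mri_anchors[trial] = {}
        for feat in mri_feats:
            vals = grp[feat].astype(float).to_numpy()
            mean, sd = float(np.mean(vals)), float(np.std(vals))
            if sd <= 0:
                raise StandardizationError(
                    f"feature {feat!r} is constant within trial {trial!r}"
                )
            mri_anchors[trial][feat] = (mean, sd)
    ref_anchors = {feat: mri_anchors[reference_trial_id][feat] for feat in mri_feats}

    prep = FittedPreprocessor(
        schema=schema,
        reference_trial_id=reference_trial_id,
        mri_anchors=mri_anchors,
        ref_anchors=ref_anchors,
        standardize_stats={f: (0.0, 1.0) for f in schema.names},
        log_eps=log_eps,
    )
    # run the pre-standardization part of the pipeline on the training rows,
    # then fit the standardization statistics
    staged = prep.transform_frame(train)
    stats: dict[str, tuple[float, float]] = {}
    for feat in schema.names:
        if schema[feat].kind == "binary":
            stats[feat] = (0.0, 1.0)
            continue
        vals = staged[feat].to_numpy()
        mean, sd = float(np.mean(vals)), float(np.std(vals))
        if sd <= 0:
            raise StandardizationError(
                f"feature {feat!r} is constant on the training split"
            )
        stats[feat] = (mean, sd)
    prep.standardize_stats = stats
    return prep


def fit_transform(
    dataset: TrialDataset,
    schema: FeatureSchema | None = None,
    reference_trial_id: str | None = None,
    training_ids: Sequence[str] | None = None,
    log_eps: float = 0.01,
    inclusion: Callable[[pd.Series], bool] | None = None,
) -> tuple[FittedPreprocessor, pd.DataFrame]:
    """Fit the preprocessor on ``training_ids`` and transform the full dataset."""
    prep = fit_preprocessor(
        dataset, schema, reference_trial_id, training_ids, log_eps, inclusion
    )
    return prep, prep.transform(dataset)
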