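"""Shared fixtures: hand-built patients and small synthetic cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from msenrich.trial_data import (
    PatientRecord,
    TrialDataset,
    Visit,
    WEEK_YEARS,
    default_schema,
)

BASE_FEATURES = {
    "age": 45.0,
    "sex": 1.0,
    "height": 170.0,
    "weight": 72.0,
    "disease_duration": 6.5,
    "edss": 4.0,
    "fss_bowel_bladder": 1.0,
    "fss_brainstem": 1.0,
    "fss_cerebellar": 2.0,
    "fss_cerebral": 1.0,
    "fss_pyramidal": 3.0,
    "fss_sensory": 2.0,
    "fss_visual": 1.0,
    "t25fw": 12.0,
    "nhpt_dominant": 30.0,
    "nhpt_nondominant": 33.0,
    "gad_count": 1.0,
    "t2_lesion_volume": 10.0,
    "nbv": 1.45,
}

ARMS = {
    "treatment": {"name": "active", "is_control": False},
    "placebo": {"name": "placebo", "is_control": True},
}


def weeks(*ws):
    """Visit times in years from week numbers."""
    return [w * WEEK_YEARS for w in ws]


def make_visits(times, edss):
    return [Visit(float(t), float(e)) for t, e in zip(times, edss)]


def make_record(pid="P1", trial="TRIAL_A", arm="treatment", features=None, visits=None):
    feats = dict(BASE_FEATURES)
    if features:
        feats.update(features)
    if visits is None:
        visits = make_visits(weeks(0, 24, 48), [4.0, 4.0, 4.5])
    return PatientRecord(pid, trial, arm, feats, visits)


def make_dataset(records, arms=None, trials=None):
    return TrialDataset(list(records), arms or dict(ARMS), trials or {})


@pytest.fixture
def two_patient_csvs(tmp_path):
    """Baseline + visits CSVs for a minimal two-patient cohort."""
    schema = default_schema()
    rows = []
    for pid, arm, overrides in [
        ("P1", "treatment", {}),
        ("P2", "placebo", {"age": 52.0, "gad_count": 3.0}),
    ]:
        feats = dict(BASE_FEATURES)
        feats.update(overrides)
        rows.append({"patient_id": pid, "trial_id": "TRIAL_A", "arm_id": arm, **feats})
    baseline = tmp_path / "patients.csv"
    pd.DataFrame(rows)[["patient_id", "trial_id", "arm_id", *schema.names]].to_csv(
        baseline, index=False
    )
    visits = tmp_path / "visits.csv"
    pd.DataFrame(
        {
            # deliberately unsorted for P1 to exercise sorting on load
            "patient_id": ["P1", "P1", "P1", "P2", "P2"],
            "time_years": [1.0, 0.0, 0.5, 0.0, 1.0],
            "edss": [5.0, 4.0, 4.5, 3.0, 3.5],
        }
    ).to_csv(visits, index=False)
    return baseline, visits
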