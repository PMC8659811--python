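"""Decision values, staging lookup, treatment rules, efficacy reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nsclc_staging import (
    CATEGORIES,
    StagingMap,
    assess_treatment,
    decision_value,
    load_treatment_trajectory,
    predict_stage,
    recommend_treatment,
    stage_from_decision_value,
)
from nsclc_staging.records import PatientRecord

CAT_ORDER = {c: i for i, c in enumerate(CATEGORIES)}


@pytest.mark.parametrize(
    "value,expected",
    [
        (233.52, "IV"),   # worked clinical example: far above 180
        (10.0, "healthy"),
        (67.75, "II"),
        (30.0, "I"),
        (119.0, "III"),   # shared endpoint assigned upward
        (180.0, "III"),   # stage III interval closed on the right
        (180.0001, "IV"),
        (57.5, "I"),      # printed gap 57-58 closed upward
        (0.0, "healthy"),
    ],
)
def test_stage_lookup(value, expected):
    assert stage_from_decision_value(value) == expected


def test_negative_decision_value_rejected():
    with pytest.raises(ValueError):
        stage_from_decision_value(-1.0)


def test_stage_lookup_is_monotone():
    grid = np.linspace(0, 500, 2001)
    stages = [CAT_ORDER[stage_from_decision_value(v)] for v in grid]
    assert all(a <= b for a, b in zip(stages, stages[1:]))


def test_staging_map_validation():
    with pytest.raises(ValueError):
        StagingMap(healthy_hi=60.0, i_hi=58.0)


def test_forced_winner_lands_in_stage_interval():
    v = decision_value({"I": 0.0, "II": 0.0, "III": 0.0, "IV": 1.0})
    assert 180.0 < v <= 400.0
    assert stage_from_decision_value(v) == "IV"


def test_all_low_confidence_is_healthy():
    v = decision_value({"I": 0.4, "II": 0.3, "III": 0.2, "IV": 0.1})
    assert v < 18.0
    assert stage_from_decision_value(v) == "healthy"


def test_decision_value_input_validation():
    with pytest.raises(ValueError):
        decision_value({})
    with pytest.raises(ValueError):
        decision_value({"I": 1.2})


@settings(max_examples=500, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4))
def test_decision_value_round_trip(etas):
    conf = dict(zip(("I", "II", "III", "IV"), etas))
    v = decision_value(conf)
    stage = stage_from_decision_value(v)
    best = max(conf.values())
    if best < 0.5:
        assert stage == "healthy"
    else:
        winners = {s for s, e in conf.items() if e == best}
        assert stage in winners


@pytest.mark.parametrize(
    "stage,profile,primary",
    [
        ("II", "coarse", "surgery"),
        ("I", "coarse", "surgery"),
        ("III", "coarse", "radiochemotherapy"),
        ("IV", "fine", "chemotherapy"),
        ("III", "fine", "radiation_therapy"),
        ("healthy", "coarse", "further_tests"),
    ],
)
def test_treatment_rules(stage, profile, primary):
    assert recommend_treatment(stage, profile).primary == primary


def test_advanced_stage_gets_adjuvant_surgery():
    plan = recommend_treatment("IV", "coarse")
    assert plan.adjuvant == "surgery"


def test_unknown_profile_or_stage_rejected():
    with pytest.raises(ValueError):
        recommend_treatment("II", "nope")
    with pytest.raises(ValueError):
        recommend_treatment("V")


def test_predict_stage_readout():
    p = predict_stage("p1", {"I": 0.1, "II": 0.2, "III": 0.3, "IV": 0.9})
    assert p.stage == "IV" and p.is_nsclc
    assert p.treatment.primary == "radiochemotherapy"
    healthy = predict_stage("p2", {"I": 0.1, "II": 0.1, "III": 0.1, "IV": 0.1})
    assert healthy.stage == "healthy" and not healthy.is_nsclc


def test_trajectory_efficacy_endpoints():
    report = assess_treatment(load_treatment_trajectory())
    first, last, decreased = report.marker_changes["CEA"]
    assert (first, last, decreased) == (285.41, 21.17, True)
    first, last, decreased = report.marker_changes["CA-125"]
    assert (first, last, decreased) == (711.01, 178.20, True)
    first, last, decreased = report.marker_changes["CYFRA21-1"]
    assert (first, last, decreased) == (4.16, 3.89, True)


def test_constant_trajectory_shows_no_decrease():
    recs = [PatientRecord(patient_id="x", markers={"CEA": 2.0}, exam_index=i)
            for i in (1, 2, 3)]
    report = assess_treatment(recs)
    assert report.marker_changes["CEA"] == (2.0, 2.0, False)
    assert report.effective is None


def test_trajectory_too_short_errors():
    with pytest.raises(ValueError):
        assess_treatment([PatientRecord(patient_id="x", markers={})])


def test_marker_missing_from_some_exams_is_indeterminate():
    recs = [
        PatientRecord(patient_id="x", markers={"CEA": 9.0, "NSE": 20.0}, exam_index=1),
        PatientRecord(patient_id="x", markers={"CEA": 4.0}, exam_index=2),
    ]
    report = assess_treatment(recs)
    assert report.marker_changes["CEA"] == (9.0, 4.0, True)
    assert report.marker_changes["NSE"][2] is None


def test_decision_value_delta_drives_effectiveness():
    recs = [PatientRecord(patient_id="x", markers={"CEA": v}, exam_index=i)
            for i, v in ((1, 300.0), (2, 20.0))]
    before = predict_stage("x", {"I": 0, "II": 0, "III": 0, "IV": 1.0})
    after = predict_stage("x", {"I": 0.7, "II": 0, "III": 0, "IV": 0})
    report = assess_treatment(recs, [before, after], threshold=40.0)
    assert report.delta == pytest.approx(
        report.decision_value_after - report.decision_value_before)
    assert report.effective is True
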