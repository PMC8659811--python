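"""Decision values, staging categories, treatment rules, efficacy tracking.

The staging score ("decision value") lives on a clinical scale partitioned
into contiguous intervals: below 18 the patient is read as healthy
(non-NSCLC, pending confirmatory tests), 18–58 stage I, 58–119 stage II,
119–180 stage III (both endpoints included on the right), above 180 stage
IV. A model's per-stage confidences are mapped onto this scale by
interpolating the winning stage's confidence across its interval, which
guarantees the round trip: the stage read back from the decision value is
the highest-confidence stage.

Treatment recommendations are a configurable rule table: the coarse
default recommends surgery for operable early disease (I/II) and
radiochemotherapy with adjuvant surgery for advanced disease (III/IV); the
fine per-stage profile matches trajectory-style monitoring (IV
chemotherapy, III radiation, II surgery, I late-stage drugs). Treatment
efficacy is assessed by comparing marker values and decision values before
and after treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .records import PatientRecord

__all__ = [
    "CATEGORIES",
    "StagingMap",
    "StagePrediction",
    "TreatmentPlan",
    "EfficacyReport",
    "stage_from_decision_value",
    "decision_value",
    "recommend_treatment",
    "assess_treatment",
    "predict_stage",
]

CATEGORIES: tuple[str, ...] = ("healthy", "I", "II", "III", "IV")
_CAT_ORDER = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class StagingMap:
    """Partition of the decision-value axis into staging categories.

    healthy [0, healthy_hi) | I [healthy_hi, i_hi) | II [i_hi, ii_hi) |
    III [ii_hi, iii_hi] | IV (iii_hi, inf). The published clinical ranges
    leave a one-unit gap between I and II and share the II/III endpoint;
    the gap is closed upward and the shared endpoint 119 is assigned to
    III so the lookup is a total function. ``iv_cap`` bounds the open
    stage-IV interval for confidence interpolation only.
    """

    healthy_hi: float = 18.0
    i_hi: float = 58.0
    ii_hi: float = 119.0
    iii_hi: float = 180.0
    iv_cap: float = 400.0

    def __post_init__(self):
        bounds = (0.0, self.healthy_hi, self.i_hi, self.ii_hi,
                  self.iii_hi, self.iv_cap)
        if any(a >= b for a, b in zip(bounds, bounds[1:])):
            raise ValueError("staging boundaries must be strictly increasing")

    def stage_of(self, v: float) -> str:
        if v < 0:
            raise ValueError("decision value must be non-negative")
        if v < self.healthy_hi:
            return "healthy"
        if v < self.i_hi:
            return "I"
        if v < self.ii_hi:
            return "II"
        if v <= self.iii_hi:          # 119 and 180 both read as stage III
            return "III"
        return "IV"

    def interval(self, category: str) -> tuple[float, float]:
        """Interpolation interval [a, b) whose points all map to ``category``."""
        table = {
            "healthy": (0.0, self.healthy_hi),
            "I": (self.healthy_hi, self.i_hi),
            "II": (self.i_hi, self.ii_hi),
            "III": (self.ii_hi, self.iii_hi),
            "IV": (float(np.nextafter(self.iii_hi, np.inf)), self.iv_cap),
        }
        return table[category]


@dataclass
class TreatmentPlan:
    primary: str
    adjuvant: str | None = None


@dataclass
class StagePrediction:
    """Staged read-out for one record."""

    patient_id: str
    confidences: dict[str, float]
    decision_value: float
    stage: str
    treatment: TreatmentPlan
    is_nsclc: bool


@dataclass
class EfficacyReport:
    """Before/after comparison along one patient's treatment trajectory.

    ``marker_changes`` maps marker -> (first, last, decreased); a marker
    observed fewer than twice gets (first-or-None, last-or-None, None) and
    is excluded from any summary. ``effective`` is None when no decision
    values were supplied."""

    marker_changes: dict[str, tuple[float | None, float | None, bool | None]]
    decision_value_before: float | None = None
    decision_value_after: float | None = None
    delta: float | None = None
    effective: bool | None = None


def stage_from_decision_value(v: float, staging_map: StagingMap | None = None) -> str:
    """Category of a decision value (total function on v >= 0)."""
    return (staging_map or StagingMap()).stage_of(float(v))


def decision_value(
    confidences: Mapping[str, float],
    staging_map: StagingMap | None = None,
    nsclc_threshold: float = 0.5,
) -> float:
    """Map per-stage confidences onto the decision-value scale.

    If the best confidence is below ``nsclc_threshold`` the value falls in
    the healthy interval (scaled by confidence); otherwise the winning
    stage's confidence, rescaled from [threshold, 1] to [0, 1), is
    interpolated across that stage's interval. Round trip guaranteed:
    ``stage_from_decision_value(decision_value(c))`` is the argmax stage
    (ties broken toward the later stage).
    """
    staging_map = staging_map or StagingMap()
    if not confidences:
        raise ValueError("confidence map is empty")
    for s, eta in confidences.items():
        if not 0.0 <= eta <= 1.0:
            raise ValueError(f"confidence for {s} outside [0, 1]: {eta}")
    best_eta = max(confidences.values())
    shrink = 1.0 - 1e-9  # keep interpolated values strictly inside [a, b)
    if best_eta < nsclc_threshold:
        return (best_eta / nsclc_threshold) * staging_map.healthy_hi * shrink
    winner = max(
        (s for s in confidences if confidences[s] == best_eta),
        key=lambda s: _CAT_ORDER[s],
    )
    frac = (best_eta - nsclc_threshold) / (1.0 - nsclc_threshold)
    a, b = staging_map.interval(winner)
    return a + frac * (b - a) * shrink


_RULES: dict[str, dict[str, TreatmentPlan]] = {
    # operable early disease vs advanced comprehensive strategy
    "coarse": {
        "healthy": TreatmentPlan("further_tests"),
        "I": TreatmentPlan("surgery"),
        "II": TreatmentPlan("surgery"),
        "III": TreatmentPlan("radiochemotherapy", adjuvant="surgery"),
        "IV": TreatmentPlan("radiochemotherapy", adjuvant="surgery"),
    },
    # finer per-stage rule used when tracking a treatment trajectory
    "fine": {
        "healthy": TreatmentPlan("further_tests"),
        "I": TreatmentPlan("late_stage_drugs"),
        "II": TreatmentPlan("surgery"),
        "III": TreatmentPlan("radiation_therapy"),
        "IV": TreatmentPlan("chemotherapy"),
    },
}


def recommend_treatment(stage: str, profile: str = "coarse") -> TreatmentPlan:
    """Deterministic treatment recommendation for a staging category."""
    try:
        table = _RULES[profile]
    except KeyError:
        raise ValueError(f"unknown treatment profile {profile!r}") from None
    if stage not in table:
        raise ValueError(f"unknown staging category {stage!r}")
    return table[stage]


def predict_stage(
    patient_id: str,
    confidences: Mapping[str, float],
    staging_map: StagingMap | None = None,
    profile: str = "coarse",
    nsclc_threshold: float = 0.5,
) -> StagePrediction:
    """Full read-out: decision value, stage, treatment, NSCLC flag."""
    staging_map = staging_map or StagingMap()
    v = decision_value(confidences, staging_map, nsclc_threshold)
    stage = staging_map.stage_of(v)
    return StagePrediction(
        patient_id=patient_id,
        confidences={s: float(e) for s, e in confidences.items()},
        decision_value=v,
        stage=stage,
        treatment=recommend_treatment(stage, profile),
        is_nsclc=stage != "healthy",
    )


def assess_treatment(
    trajectory: Sequence[PatientRecord],
    predictions: Sequence[StagePrediction] | None = None,
    threshold: float = 40.0,
) -> EfficacyReport:
    """Compare markers (and decision values, when supplied) before vs
    after treatment along a trajectory ordered by exam_index.

    The per-marker ``decreased`` flag is last < first over the exams where
    the marker was observed; markers observed fewer than twice are
    indeterminate. ``effective`` is decision-value delta <= -threshold
    (default 40, one early staging-interval width).
    """
    if len(trajectory) < 2:
        raise ValueError("a trajectory needs at least two examinations")
    records = sorted(trajectory, key=lambda r: r.exam_index)
    markers = sorted({m for r in records for m in r.markers})
    changes: dict[str, tuple[float | None, float | None, bool | None]] = {}
    for m in markers:
        seen = [r.markers[m] for r in records if m in r.markers]
        if len(seen) < 2:
            only = seen[0] if seen else None
            changes[m] = (only, only, None)
        else:
            changes[m] = (seen[0], seen[-1], seen[-1] < seen[0])
    report = EfficacyReport(marker_changes=changes)
    if predictions is not None:
        if len(predictions) != len(records):
            raise ValueError("one prediction per examination is required")
        before = float(predictions[0].decision_value)
        after = float(predictions[-1].decision_value)
        report.decision_value_before = before
        report.decision_value_after = after
        report.delta = after - before
        report.effective = report.delta <= -threshold
    return report
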