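"""Synthetic patient cohorts and their text rendering.

Non-small cell lung cancer (NSCLC) staging from medical-record text needs
labelled records; real hospital records are not distributable, so this
module generates seeded synthetic cohorts whose tumor-marker panels follow
the published normal reference ranges and the clinical pattern that marker
elevation above the reference upper limit grows more frequent and more
extreme with advancing stage (III/IV-majority imbalance is the default).

A record is rendered to a deterministic token sequence (``render_text``)
for the embedding/CNN pipeline: each marker contributes a categorical token
(normal / high / very_high, cut at the reference upper limit and at ten
times that limit), demographics and symptoms contribute further tokens.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._rng import stream

__all__ = [
    "MARKERS",
    "HIGH_RELEVANCE_MARKERS",
    "STAGES",
    "NormalRanges",
    "PatientRecord",
    "CohortConfig",
    "generate_cohort",
    "render_text",
    "records_to_jsonl",
    "records_from_jsonl",
    "records_to_csv",
    "records_from_csv",
    "load_marker_group_means",
    "load_treatment_trajectory",
]

#: Canonical marker panel (name -> unit).
MARKERS: dict[str, str] = {
    "CYFRA21-1": "ug/mL",
    "CEA": "ug/L",
    "CA-125": "KU/L",
    "NSE": "ug/mL",
    "CA242": "KU/L",
    "PSA": "ug/mL",
    "HGH": "ug/mL",
    "Free-PSA": "ug/mL",
    "FERRITIN": "KU/L",
}

#: The three markers with the highest diagnostic weight for NSCLC staging.
HIGH_RELEVANCE_MARKERS: tuple[str, ...] = ("CYFRA21-1", "CEA", "CA-125")

STAGES: tuple[str, ...] = ("I", "II", "III", "IV")

_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "CYFRA21-1": (0.0, 1.80),
    "CEA": (0.0, 5.00),
    "CA-125": (0.0, 35.00),
    "NSE": (0.0, 13.00),
    "CA242": (0.0, 20.00),
    "PSA": (0.0, 5.00),
    "HGH": (0.0, 7.50),
    "Free-PSA": (0.0, 1.00),
    # FERRITIN has no published range in the panel tables; conventional
    # serum upper reference used so every marker can be tokenized.
    "FERRITIN": (0.0, 400.0),
}

_SYMPTOM_POOL_EARLY = ("cough", "fatigue", "chest_tightness")
_SYMPTOM_POOL_LATE = ("chest_pain", "hemoptysis", "dyspnea", "weight_loss")

# Probability that a high-relevance marker is elevated above its reference
# upper limit, by stage; elevation frequency rises with stage.
_P_ABNORMAL_HIGH = {"I": 0.60, "II": 0.75, "III": 0.90, "IV": 0.97}
_P_ABNORMAL_LOW = {"I": 0.15, "II": 0.25, "III": 0.35, "IV": 0.45}


@dataclass(frozen=True)
class NormalRanges:
    """Closed reference interval [lo, hi] per marker, in that marker's unit."""

    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"range for {name} has lo > hi: [{lo}, {hi}]")

    def __getitem__(self, marker: str) -> tuple[float, float]:
        try:
            return self.ranges[marker]
        except KeyError:
            raise KeyError(f"no reference range for marker {marker!r}") from None

    def upper(self, marker: str) -> float:
        return self[marker][1]


@dataclass
class PatientRecord:
    """One patient's examination record.

    ``stages`` is a *set* of stage labels in {I, II, III, IV}: records at
    a clinically ambiguous transition may carry two adjacent stage labels,
    and an empty set means non-NSCLC. ``exam_index`` orders repeated exams
    of the same patient along a treatment trajectory (1-based).
    """

    patient_id: str
    markers: dict[str, float]
    age: int = 50
    gender: str = "female"
    smoking_years: int = 0
    family_history: bool = False
    symptoms: list[str] = field(default_factory=list)
    stages: set[str] = field(default_factory=set)
    exam_index: int = 1

    def __post_init__(self) -> None:
        for name, value in self.markers.items():
            if value < 0:
                raise ValueError(f"negative marker value {name}={value}")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels {sorted(bad)}")
        if self.exam_index < 1:
            raise ValueError("exam_index must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for one synthetic cohort.

    ``stage_proportions`` may sum to less than 1; the remainder becomes
    non-NSCLC (healthy) records. ``cooccurrence_rate`` is the probability
    that a staged record also carries an adjacent second stage label.
    ``severity_multipliers`` scale the log-normal median of an elevated
    high-relevance marker relative to its reference upper limit.
    """

    n_patients: int = 2000
    stage_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.05, "II": 0.10, "III": 0.35, "IV": 0.40}
    )
    cooccurrence_rate: float = 0.15
    severity_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"I": 1.5, "II": 3.0, "III": 8.0, "IV": 15.0}
    )
    noise_cv: float = 0.35
    age_range: tuple[int, int] = (45, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        props = dict(self.stage_proportions)
        if any(p < 0 for p in props.values()):
            raise ValueError("stage proportions must be non-negative")
        if sum(props.values()) > 1.0 + 1e-9:
            raise ValueError("stage proportions must sum to at most 1")
        unknown = set(props) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in proportions: {sorted(unknown)}")
        if not 0.0 <= self.cooccurrence_rate <= 1.0:
            raise ValueError("cooccurrence_rate must be in [0, 1]")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")


def _lognormal(rng: np.random.Generator, median: float, cv: float) -> float:
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(median * np.exp(sigma * rng.standard_normal()))


def _draw_markers(
    rng: np.random.Generator,
    stage: str | None,
    ranges: NormalRanges,
    severity: Mapping[str, float],
    cv: float,
) -> dict[str, float]:
    """Stage-conditional marker panel.

    Healthy draws sit around 40% of the reference upper limit (right-skewed,
    non-negative); elevated draws sit around ``severity[stage]`` times the
    upper limit for high-relevance markers and a milder factor for the rest.
    """
    out: dict[str, float] = {}
    for name in MARKERS:
        hi = ranges.upper(name)
        base_median = 0.4 * hi if hi > 0 else 0.1
        if stage is None:
            out[name] = _lognormal(rng, base_median, cv)
            continue
        high = name in HIGH_RELEVANCE_MARKERS
        p_abn = (_P_ABNORMAL_HIGH if high else _P_ABNORMAL_LOW)[stage]
        if rng.random() < p_abn:
            mult = severity[stage] if high else 1.0 + 0.25 * (severity[stage] - 1.0)
            out[name] = _lognormal(rng, mult * hi, cv)
        else:
            out[name] = _lognormal(rng, base_median, cv)
    return out


def _draw_stages(rng: np.random.Generator, config: CohortConfig) -> set[str]:
    props = {s: config.stage_proportions.get(s, 0.0) for s in STAGES}
    u = rng.random()
    acc = 0.0
    primary: str | None = None
    for s in STAGES:
        acc += props[s]
        if u < acc:
            primary = s
            break
    if primary is None:
        return set()
    labels = {primary}
    if rng.random() < config.cooccurrence_rate:
        idx = STAGES.index(primary)
        neighbours = [STAGES[j] for j in (idx - 1, idx + 1) if 0 <= j < 4]
        labels.add(neighbours[int(rng.integers(len(neighbours)))])
    return labels


def generate_cohort(
    config: CohortConfig, ranges: NormalRanges | None = None
) -> list[PatientRecord]:
    """Generate a seeded synthetic cohort of patient records.

    Deterministic for a fixed config (the seed lives in the config). Stage
    frequencies converge to ``config.stage_proportions``; a staged record's
    high-relevance markers exceed their reference upper limits with a
    probability that increases with stage, while non-NSCLC records stay
    within range with high probability.
    """
    ranges = ranges or NormalRanges()
    rng = stream(config.seed, "cohort")
    lo_age, hi_age = config.age_range
    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        stages = _draw_stages(rng, config)
        worst = max((STAGES.index(s) for s in stages), default=-1)
        stage = STAGES[worst] if worst >= 0 else None
        markers = _draw_markers(
            rng, stage, ranges, config.severity_multipliers, config.noise_cv
        )
        n_sym_mean = 0.5 if stage is None else 1.0 + STAGES.index(stage)
        n_sym = int(rng.poisson(n_sym_mean))
        pool = list(_SYMPTOM_POOL_EARLY)
        if stage in ("III", "IV"):
            pool += list(_SYMPTOM_POOL_LATE)
        n_sym = min(n_sym, len(pool))
        symptoms = sorted(
            rng.choice(pool, size=n_sym, replace=False).tolist()
        ) if n_sym else []
        smoking = 0 if rng.random() < 0.4 else int(rng.integers(1, 41))
        records.append(
            PatientRecord(
                patient_id=f"P{i:06d}",
                markers=markers,
                age=int(rng.integers(lo_age, hi_age + 1)),
                gender="male" if rng.random() < 0.5 else "female",
                smoking_years=smoking,
                family_history=bool(rng.random() < 0.15),
                symptoms=symptoms,
                stages=stages,
            )
        )
    return records


def _marker_token_key(name: str) -> str:
    return name.lower().replace("-", "_").replace(".", "_")


def render_text(
    record: PatientRecord,
    ranges: NormalRanges | None = None,
    include_raw: bool = False,
) -> list[str]:
    """Render a record as a deterministic token sequence.

    Marker values are discretized against the reference interval upper
    limit ``hi``: ``normal`` (value <= hi), ``high`` (hi < value <= 10*hi),
    ``very_high`` (value > 10*hi) — the ten-fold cut mirrors the clinical
    reading of a marker "more than ten times" over its critical value.
    Demographics and symptoms contribute categorical tokens; the vocabulary
    is finite and closed under the generator.
    """
    ranges = ranges or NormalRanges()
    tokens: list[str] = []
    for name in record.markers:
        hi = ranges.upper(name)  # KeyError for unknown markers
        value = record.markers[name]
        if value <= hi:
            level = "normal"
        elif value <= 10.0 * hi:
            level = "high"
        else:
            level = "very_high"
        key = _marker_token_key(name)
        tokens.append(f"{key}={level}")
        if include_raw:
            tokens.append(f"{key}_raw={value:.2f}")
    tokens.append(f"age_band={5 * (record.age // 5)}")
    tokens.append(f"gender={record.gender}")
    if record.smoking_years == 0:
        smoking = "never"
    elif record.smoking_years <= 10:
        smoking = "short"
    elif record.smoking_years <= 25:
        smoking = "medium"
    else:
        smoking = "long"
    tokens.append(f"smoking={smoking}")
    tokens.append(f"family_history={'yes' if record.family_history else 'no'}")
    tokens.extend(f"symptom={s}" for s in record.symptoms)
    return tokens


# ---------------------------------------------------------------------------
# serialization


def _record_to_dict(record: PatientRecord) -> dict:
    d = asdict(record)
    d["stages"] = sorted(record.stages, key=STAGES.index)
    return d


def _record_from_dict(d: dict) -> PatientRecord:
    d = dict(d)
    d["stages"] = set(d.get("stages") or [])
    d["symptoms"] = list(d.get("symptoms") or [])
    return PatientRecord(**d)


def records_to_jsonl(records: Iterable[PatientRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_dict(rec), sort_keys=True) + "\n")


def records_from_jsonl(path) -> list[PatientRecord]:
    with open(path) as fh:
        return [_record_from_dict(json.loads(line)) for line in fh if line.strip()]


_CSV_FIELDS = [
    "patient_id", "age", "gender", "smoking_years", "family_history",
    "symptoms", "stages", "exam_index",
]


def records_to_csv(records: Iterable[PatientRecord], path) -> None:
    """One column per scalar field plus one column per marker; list fields
    are semicolon-joined."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS + list(MARKERS))
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id, rec.age, rec.gender, rec.smoking_years,
                    int(rec.family_history), ";".join(rec.symptoms),
                    ";".join(sorted(rec.stages, key=STAGES.index)),
                    rec.exam_index,
                ]
                + [repr(rec.markers.get(m, "")) for m in MARKERS]
            )


def records_from_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        markers = {
            m: float(row[m]) for m in MARKERS if m in df.columns and row[m] != ""
        }
        out.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                markers=markers,
                age=int(row["age"]),
                gender=str(row["gender"]),
                smoking_years=int(row["smoking_years"]),
                family_history=bool(int(row["family_history"])),
                symptoms=[s for s in str(row["symptoms"]).split(";") if s],
                stages={s for s in str(row["stages"]).split(";") if s},
                exam_index=int(row["exam_index"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# bundled reference examples


def _data_path(name: str):
    return resources.files("nsclc_staging").joinpath("data", name)


def load_marker_group_means() -> pd.DataFrame:
    """Published mean marker panels for three symptomatic patient groups,
    five examinations each (columns: group, exam, then the 9 markers)."""
    with resources.as_file(_data_path("marker_group_means.csv")) as p:
        return pd.read_csv(p)


def load_treatment_trajectory() -> list[PatientRecord]:
    """Published marker panel of one patient followed over eight exams
    across diagnosis, treatment and follow-up, as PatientRecords ordered
    by exam_index."""
    with resources.as_file(_data_path("treatment_trajectory.csv")) as p:
        df = pd.read_csv(p)
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id="trajectory-patient",
                markers={m: float(row[m]) for m in MARKERS},
                age=52,
                exam_index=int(row["exam_index"]),
            )
        )
    return sorted(records, key=lambda r: r.exam_index)
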