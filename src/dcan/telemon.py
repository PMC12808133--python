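"""Telemonitoring table I/O and cohort description.

The raw data model mirrors the UCI Parkinsons Telemonitoring CSV dialect:
one row per at-home voice assessment, carrying the subject identifier,
demographics, the time of the test in days since recruitment, the motor and
total UPDRS scores, and 16 precomputed acoustic dysphonia measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DomainError, ParseError, SchemaError

#: The 16 acoustic measures, in canonical UCI column order.
VOICE_FEATURES: tuple[str, ...] = (
    "Jitter(%)",
    "Jitter(Abs)",
    "Jitter:RAP",
    "Jitter:PPQ5",
    "Jitter:DDP",
    "Shimmer",
    "Shimmer(dB)",
    "Shimmer:APQ3",
    "Shimmer:APQ5",
    "Shimmer:APQ11",
    "Shimmer:DDA",
    "NHR",
    "HNR",
    "RPDE",
    "DFA",
    "PPE",
)

#: Full column set of the CSV dialect, in canonical order.
CSV_COLUMNS: tuple[str, ...] = (
    "subject#",
    "age",
    "sex",
    "test_time",
    "motor_UPDRS",
    "total_UPDRS",
) + VOICE_FEATURES

#: Days per mean Gregorian month, used for monitoring-duration conversion.
DAYS_PER_MONTH = 30.44

#: UCI sex coding. The integer code stored in the CSV maps to these labels.
SEX_CODES = {0: "male", 1: "female"}

STAGES = ("Early", "Moderate", "Advanced")


@dataclass(frozen=True)
class VisitRecord:
    """One telemonitoring assessment of one subject."""

    subject_id: str
    age: int
    sex: int  # 0 = male, 1 = female (UCI convention, see SEX_CODES)
    test_time: float  # days since recruitment; may be fractional
    motor_updrs: float
    total_updrs: float
    voice: dict[str, float] = field(compare=True)

    def __post_init__(self) -> None:
        missing = [f for f in VOICE_FEATURES if f not in self.voice]
        if missing:
            raise SchemaError(f"visit record missing acoustic measures: {missing}")
        if not math.isfinite(self.motor_updrs):
            raise DomainError("motor_updrs must be finite")
        if not math.isfinite(self.test_time):
            raise DomainError("test_time must be finite")


@dataclass(frozen=True)
class PatientSeries:
    """All visits of one subject, sorted ascending by test_time."""

    subject_id: str
    visits: tuple[VisitRecord, ...]

    def __post_init__(self) -> None:
        if len(self.visits) < 1:
            raise DomainError("a patient series needs at least one visit")
        if any(v.subject_id != self.subject_id for v in self.visits):
            raise ConsistencyError("mixed subject ids within one series")
        times = [v.test_time for v in self.visits]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ConsistencyError("visits must be sorted by test_time")

    def __len__(self) -> int:
        return len(self.visits)

    @property
    def times(self) -> np.ndarray:
        return np.array([v.test_time for v in self.visits], dtype=float)

    @property
    def motor_updrs(self) -> np.ndarray:
        return np.array([v.motor_updrs for v in self.visits], dtype=float)

    def voice_trace(self, feature: str) -> np.ndarray:
        return np.array([v.voice[feature] for v in self.visits], dtype=float)


@dataclass
class CohortSummary:
    """Cohort-level demographic and acoustic description (Table-1 style)."""

    n_patients: int
    n_records: int
    age_mean: float
    age_sd: float
    n_male: int
    n_female: int
    stage_counts: dict[str, int]
    duration_mean: float  # months
    duration_sd: float  # months
    voice_means: dict[str, tuple[float, float]]  # feature -> (mean, sd) across patients

    def __post_init__(self) -> None:
        assert self.n_male + self.n_female == self.n_patients
        assert sum(self.stage_counts.values()) == self.n_patients

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_records": self.n_records,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "n_male": self.n_male,
            "n_female": self.n_female,
            "stage_counts": dict(self.stage_counts),
            "duration_mean_months": self.duration_mean,
            "duration_sd_months": self.duration_sd,
            "voice_means": {k: list(v) for k, v in self.voice_means.items()},
        }


def _normalize(name: str) -> str:
    return "".join(name.split()).lower()


def read_telemonitoring_table(path) -> list[VisitRecord]:
    """Read a telemonitoring CSV into a list of :class:`VisitRecord`.

    Column matching is order-insensitive and tolerant of whitespace/case
    differences in the header. Row order is preserved.

    Raises
    ------
    SchemaError
        If an expected column is absent (names the column).
    ParseError
        If a cell is not numeric (names the row index).
    """
    frame = pd.read_csv(path, dtype=str)
    lookup = {_normalize(c): c for c in frame.columns}
    colmap: dict[str, str] = {}
    for want in CSV_COLUMNS:
        key = _normalize(want)
        if key not in lookup:
            raise SchemaError(f"missing column: {want!r}")
        colmap[want] = lookup[key]

    records: list[VisitRecord] = []
    for idx in range(len(frame)):
        values: dict[str, float] = {}
        for want in CSV_COLUMNS[1:]:
            raw = frame.at[idx, colmap[want]]
            try:
                values[want] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"non-numeric value {raw!r} in column {want!r} at data row {idx}"
                ) from exc
        subject = str(frame.at[idx, colmap["subject#"]]).strip()
        records.append(
            VisitRecord(
                subject_id=subject,
                age=int(values["age"]),
                sex=int(values["sex"]),
                test_time=values["test_time"],
                motor_updrs=values["motor_UPDRS"],
                total_updrs=values["total_UPDRS"],
                voice={f: values[f] for f in VOICE_FEATURES},
            )
        )
    return records


def _subject_sort_key(subject_id: str):
    # ascending numeric order where ids are numeric, lexicographic otherwise
    try:
        return (0, float(subject_id), subject_id)
    except ValueError:
        return (1, 0.0, subject_id)


def build_patient_series(records: list[VisitRecord]) -> list[PatientSeries]:
    """Group records by subject and sort each group by test_time.

    Series are returned in ascending subject-id order so the output is a
    deterministic function of the record *set* (input row order is
    irrelevant; ties in test_time keep input order).
    """
    groups: dict[str, list[VisitRecord]] = {}
    for rec in records:
        groups.setdefault(rec.subject_id, []).append(rec)
    series = []
    for sid in sorted(groups, key=_subject_sort_key):
        visits = groups[sid]
        ages = {v.age for v in visits}
        sexes = {v.sex for v in visits}
        if len(ages) > 1 or len(sexes) > 1:
            raise ConsistencyError(
                f"subject {sid!r} has conflicting age/sex across visits"
            )
        visits = sorted(visits, key=lambda v: v.test_time)
        series.append(PatientSeries(subject_id=sid, visits=tuple(visits)))
    return series


def classify_disease_stage(updrs: float) -> str:
    """Map a motor-UPDRS value onto the Early/Moderate/Advanced grid.

    Early covers [0, 20], Moderate (20, 40], Advanced (40, inf). The grid
    is printed for integer scores as 0-20 / 21-40 / 41+; the half-open
    convention extends it gaplessly to continuous values such as
    per-patient means.
    """
    if not math.isfinite(updrs) or updrs < 0:
        raise DomainError(f"motor-UPDRS must be finite and >= 0, got {updrs!r}")
    if updrs <= 20:
        return "Early"
    if updrs <= 40:
        return "Moderate"
    return "Advanced"


def cohort_summary(series: list[PatientSeries], stage_from: str = "mean") -> CohortSummary:
    """Compute a Table-1-style cohort summary.

    Demographics are taken once per patient; the disease stage is assigned
    from each patient's mean motor-UPDRS (``stage_from="baseline"`` uses the
    first visit instead); monitoring duration is (last - first test_time)
    converted at 30.44 days/month; acoustic summaries are per-patient means
    first, then mean and sd across patients.
    """
    if not series:
        raise DomainError("cohort_summary needs at least one patient")
    if stage_from not in ("mean", "baseline"):
        raise DomainError(f"unknown stage_from {stage_from!r}")

    ages = np.array([s.visits[0].age for s in series], dtype=float)
    sexes = np.array([s.visits[0].sex for s in series])
    stage_counts = {st: 0 for st in STAGES}
    for s in series:
        ref = float(np.mean(s.motor_updrs)) if stage_from == "mean" else s.visits[0].motor_updrs
        stage_counts[classify_disease_stage(ref)] += 1

    durations = np.array(
        [(s.times[-1] - s.times[0]) / DAYS_PER_MONTH for s in series], dtype=float
    )
    voice_means: dict[str, tuple[float, float]] = {}
    for feat in VOICE_FEATURES:
        per_patient = np.array([float(np.mean(s.voice_trace(feat))) for s in series])
        sd = float(np.std(per_patient, ddof=1)) if len(series) > 1 else 0.0
        voice_means[feat] = (float(np.mean(per_patient)), sd)

    n = len(series)
    return CohortSummary(
        n_patients=n,
        n_records=sum(len(s) for s in series),
        age_mean=float(np.mean(ages)),
        age_sd=float(np.std(ages, ddof=1)) if n > 1 else 0.0,
        n_male=int(np.sum(sexes == 0)),
        n_female=int(np.sum(sexes == 1)),
        stage_counts=stage_counts,
        duration_mean=float(np.mean(durations)),
        duration_sd=float(np.std(durations, ddof=1)) if n > 1 else 0.0,
        voice_means=voice_means,
    )


def write_telemonitoring_csv(series: list[PatientSeries], path) -> None:
    """Write a cohort back to the UCI CSV dialect at full float precision."""
    rows = []
    for s in series:
        for v in s.visits:
            row = {
                "subject#": v.subject_id,
                "age": v.age,
                "sex": v.sex,
                "test_time": v.test_time,
                "motor_UPDRS": v.motor_updrs,
                "total_UPDRS": v.total_updrs,
            }
            row.update({f: v.voice[f] for f in VOICE_FEATURES})
            rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False, float_format="%.17g")
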