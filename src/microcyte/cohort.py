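"""Patient records, cohort inclusion/exclusion, and class-balance diagnostics.

The study population is adults with hypochromic microcytic anemia in whom
iron deficiency anemia (IDA) must be told apart from beta-thalassemia trait
(BTT).  Inclusion requires microcytosis (MCV < 80 fL), hypochromia
(MCH < 27 pg) and sex-specific anemia (Hb < 12 g/dL for women, < 13 g/dL for
men); severe anemia (Hb < 8 g/dL) is excluded.  The gold-standard label is
confirmatory: HbA2 > 3.5 % defines BTT, serum ferritin < 15 ng/mL defines
IDA, and records satisfying both (simultaneous presentation) or neither rule
are excluded with an explicit reason.

All thresholds are strict inequalities, exactly as the clinical criteria are
stated; boundary cases are rejected and auditable through the rejection
report.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IDA",
    "BTT",
    "UNKNOWN",
    "PatientRecord",
    "CohortCriteria",
    "Rejection",
    "apply_inclusion_exclusion",
    "class_balance_entropy",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_rejection_report",
    "validate_record",
]

IDA = "IDA"
BTT = "BTT"
UNKNOWN = "unknown"

#: canonical CSV column order (unknown extra columns are appended after these)
CSV_COLUMNS = (
    "hb", "hct", "mcv", "mch", "mchc", "rbc", "rdw",
    "hba2", "ferritin", "serum_iron", "tibc", "sex", "label",
)

#: the seven CBC red-cell variables used by indices and trees
CBC_FIELDS = ("hb", "hct", "mcv", "mch", "mchc", "rbc", "rdw")


@dataclass
class PatientRecord:
    """One complete blood count panel with confirmatory markers.

    Units: hb g/dL, hct %, mcv fL, mch pg, mchc g/dL, rbc 10^12/L, rdw %,
    hba2 % of total Hb, ferritin ng/mL, serum_iron and tibc ug/dL.
    """

    hb: float | None = None
    hct: float | None = None
    mcv: float | None = None
    mch: float | None = None
    mchc: float | None = None
    rbc: float | None = None
    rdw: float | None = None
    hba2: float | None = None
    ferritin: float | None = None
    serum_iron: float | None = None
    tibc: float | None = None
    sex: str = "female"
    label: str = UNKNOWN
    record_id: str | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        """Numeric fields as a flat dict (for formula evaluation)."""
        return {
            name: getattr(self, name)
            for name in CSV_COLUMNS
            if name not in ("sex", "label")
        }


@dataclass(frozen=True)
class CohortCriteria:
    """Thresholds defining the study population, in the units of PatientRecord."""

    mcv_max: float = 80.0
    mch_max: float = 27.0
    hb_max_female: float = 12.0
    hb_max_male: float = 13.0
    hb_min: float = 8.0
    hba2_btt_threshold: float = 3.5
    ferritin_ida_threshold: float = 15.0

    def __post_init__(self) -> None:
        if not (self.hb_min < self.hb_max_female <= self.hb_max_male):
            raise ValueError(
                "criteria must satisfy hb_min < hb_max_female <= hb_max_male"
            )


@dataclass(frozen=True)
class Rejection:
    record_id: str
    reason: str


_REQUIRED = ("mcv", "mch", "hb", "hba2", "ferritin")


def validate_record(record: PatientRecord, mchc_rtol: float = 0.15) -> list[str]:
    """Soft validation: positivity and MCHC ~ 100*MCH/MCV consistency.

    Returns a list of warning strings (also emitted via :mod:`warnings`);
    inconsistency is never grounds for rejection because analyser-reported
    MCHC is derived from Hb/HCT, not MCH/MCV, and disagreement flags a
    transcription problem rather than an invalid patient.
    """
    notes: list[str] = []
    for f in fields(record):
        if f.name in ("sex", "label", "record_id", "extra"):
            continue
        value = getattr(record, f.name)
        if value is not None and not (value > 0):
            notes.append(f"non-positive {f.name}={value}")
    if record.mchc is not None and record.mch is not None and record.mcv is not None:
        implied = 100.0 * record.mch / record.mcv
        if abs(record.mchc - implied) > mchc_rtol * implied:
            notes.append(
                f"mchc={record.mchc:.2f} inconsistent with 100*mch/mcv={implied:.2f}"
            )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return notes


def _record_id(record: PatientRecord, position: int) -> str:
    return record.record_id if record.record_id is not None else f"#{position}"


def _screen(record: PatientRecord, c: CohortCriteria) -> str | None:
    """Return a rejection reason, or None if the record enters the cohort."""
    for name in _REQUIRED:
        value = getattr(record, name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return f"missing:{name}"
    if record.sex not in ("male", "female"):
        return "missing:sex"
    if not record.mcv < c.mcv_max:
        return "mcv"
    if not record.mch < c.mch_max:
        return "mch"
    hb_max = c.hb_max_male if record.sex == "male" else c.hb_max_female
    if not record.hb < hb_max:
        return "not anemic"
    if record.hb < c.hb_min:
        return "severe anemia"
    is_btt = record.hba2 > c.hba2_btt_threshold
    is_ida = record.ferritin < c.ferritin_ida_threshold
    if is_btt and is_ida:
        return "ambiguous"
    if not is_btt and not is_ida:
        return "unlabeled"
    return None


def apply_inclusion_exclusion(
    records: Sequence[PatientRecord],
    criteria: CohortCriteria | None = None,
) -> tuple[list[PatientRecord], list[Rejection]]:
    """Filter records by the study criteria and assign gold-standard labels.

    Returns ``(cohort, rejections)``; every input record lands in exactly one
    of the two lists, and every retained record carries its assigned label
    (BTT when HbA2 exceeds the threshold, IDA when ferritin falls below it).
    """
    if len(records) == 0:
        raise ValueError("no records supplied")
    criteria = criteria or CohortCriteria()
    cohort: list[PatientRecord] = []
    rejections: list[Rejection] = []
    for position, record in enumerate(records):
        reason = _screen(record, criteria)
        if reason is not None:
            rejections.append(Rejection(_record_id(record, position), reason))
            continue
        label = BTT if record.hba2 > criteria.hba2_btt_threshold else IDA
        cohort.append(replace(record, label=label))
    return cohort, rejections


def class_balance_entropy(labels: Iterable[str]) -> float:
    """Normalized Shannon entropy H(p)/log(k) of the label distribution.

    1.0 for perfectly balanced classes, 0.0 for a single class (k = 1, the
    0/0 case, is defined as 0).  The log base cancels in the ratio.
    """
    counts = Counter(labels)
    if not counts:
        raise ValueError("no labels supplied")
    k = len(counts)
    if k == 1:
        return 0.0
    total = sum(counts.values())
    h = -sum((n / total) * math.log(n / total) for n in counts.values())
    return h / math.log(k)


# ---------------------------------------------------------------------------
# CSV interface: one row per patient, canonical header, extras preserved.

def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    extra_cols: list[str] = []
    for position, record in enumerate(records):
        row = {"record_id": _record_id(record, position)}
        for name in CSV_COLUMNS:
            row[name] = getattr(record, name)
        for key, value in record.extra.items():
            row[key] = value
            if key not in extra_cols:
                extra_cols.append(key)
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = ["record_id", *CSV_COLUMNS, *extra_cols]
    return frame.reindex(columns=ordered)


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    known = set(CSV_COLUMNS) | {"record_id"}
    extra_cols = [c for c in frame.columns if c not in known]
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for name in CSV_COLUMNS:
            if name not in frame.columns:
                continue
            value = row[name]
            if name in ("sex", "label"):
                kwargs[name] = value if isinstance(value, str) else UNKNOWN
            else:
                kwargs[name] = None if pd.isna(value) else float(value)
        rid = row.get("record_id")
        kwargs["record_id"] = None if rid is None or pd.isna(rid) else str(rid)
        kwargs["extra"] = {c: row[c] for c in extra_cols}
        records.append(PatientRecord(**kwargs))
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    return frame_to_cohort(pd.read_csv(path))


def write_rejection_report(rejections: Sequence[Rejection], path) -> None:
    pd.DataFrame(
        [(r.record_id, r.reason) for r in rejections],
        columns=["record_id", "reason"],
    ).to_csv(path, index=False)
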