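"""Registry of published hematological discrimination indices.

Each index is a closed-form score over CBC fields with a published cutoff and
a decision direction: ``btt_side`` says which side of the cutoff predicts
beta-thalassemia trait.  The classic example is Mentzer's quotient MCV/RBC,
below 13 suggesting BTT (thalassemic blood packs many small cells, so RBC is
high relative to MCV), above 13 suggesting IDA.

Definitions are declarative data (JSON), not code, so the shipped registry
can be audited and corrected entry by entry; several entries from less
accessible primary reports are best-effort reconstructions and say so in
their ``source`` field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Sequence

import pandas as pd

from ._expr import EvaluationError, Expression
from .cohort import BTT, IDA, PatientRecord

__all__ = [
    "IndexDefinition",
    "IndexResult",
    "builtin_registry",
    "evaluate_index",
    "classify_cohort",
    "evaluable_counts",
    "load_registry",
    "save_registry",
    "EvaluationError",
]

BELOW = "below"
ABOVE = "above"
OUTSIDE = "outside-interval"


@dataclass(frozen=True)
class IndexDefinition:
    """A named formula + cutoff(s) + decision direction.

    ``cutoffs`` holds one threshold for 'below'/'above' rules and two
    (low, high) for 'outside-interval' rules, whose BTT zone is outside the
    closed interval.  Ties (value == cutoff) go to the non-BTT side.
    """

    name: str
    expression: str
    cutoffs: tuple[float, ...]
    btt_side: str
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "cutoffs", tuple(float(c) for c in self.cutoffs))
        if self.btt_side not in (BELOW, ABOVE, OUTSIDE):
            raise ValueError(f"bad btt_side {self.btt_side!r}")
        n_expected = 2 if self.btt_side == OUTSIDE else 1
        if len(self.cutoffs) != n_expected:
            raise ValueError(
                f"{self.name}: {self.btt_side} rule needs {n_expected} cutoff(s)"
            )
        object.__setattr__(self, "_compiled", Expression(self.expression))

    @property
    def fields(self) -> frozenset[str]:
        return self._compiled.fields

    def value(self, record: PatientRecord) -> float:
        return self._compiled(record.as_dict())

    def predict_value(self, value: float) -> str:
        if self.btt_side == BELOW:
            return BTT if value < self.cutoffs[0] else IDA
        if self.btt_side == ABOVE:
            return BTT if value > self.cutoffs[0] else IDA
        low, high = self.cutoffs
        return BTT if (value < low or value > high) else IDA


@dataclass(frozen=True)
class IndexResult:
    method: str
    value: float
    prediction: str


def evaluate_index(defn: IndexDefinition, record: PatientRecord) -> IndexResult:
    """Evaluate one index on one record; errors name the offending field."""
    value = defn.value(record)
    return IndexResult(defn.name, value, defn.predict_value(value))


def classify_cohort(
    registry: Sequence[IndexDefinition],
    cohort: Sequence[PatientRecord],
) -> pd.DataFrame:
    """Prediction matrix: methods as rows, patient ids as columns.

    Cells hold 'BTT'/'IDA', or 'NA:<reason>' when an index could not be
    evaluated on a record; failures never abort the run.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    ids = [
        r.record_id if r.record_id is not None else f"#{i}"
        for i, r in enumerate(cohort)
    ]
    data = {}
    for defn in registry:
        row = []
        for record in cohort:
            try:
                row.append(evaluate_index(defn, record).prediction)
            except EvaluationError as exc:
                row.append(f"NA:{exc}")
        data[defn.name] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=ids)


def evaluable_counts(predictions: pd.DataFrame) -> pd.Series:
    """Per-method count of successfully evaluated cells."""
    return (~predictions.apply(lambda col: col.str.startswith("NA:"))).sum(axis=1)


def load_registry(path) -> list[IndexDefinition]:
    with open(path, encoding="utf-8") as handle:
        raw = json.load(handle)
    return _parse_registry(raw)


def _parse_registry(raw) -> list[IndexDefinition]:
    defs = [
        IndexDefinition(
            name=entry["name"],
            expression=entry["expression"],
            cutoffs=tuple(entry["cutoffs"]),
            btt_side=entry["btt_side"],
            source=entry.get("source", ""),
        )
        for entry in raw
    ]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate index names in registry")
    return defs


def save_registry(registry: Sequence[IndexDefinition], path) -> None:
    raw = [
        {
            "name": d.name,
            "expression": d.expression,
            "cutoffs": list(d.cutoffs),
            "btt_side": d.btt_side,
            "source": d.source,
        }
        for d in registry
    ]
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(raw, handle, indent=2, ensure_ascii=False)
        handle.write("\n")


@lru_cache(maxsize=1)
def _builtin() -> tuple[IndexDefinition, ...]:
    text = resources.files("microcyte.data").joinpath("indices.json").read_text("utf-8")
    return tuple(_parse_registry(json.loads(text)))


def builtin_registry() -> list[IndexDefinition]:
    """The 43 published discrimination indices shipped with the package."""
    return list(_builtin())
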