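"""Composite score computation from per-subsite patterns.

Each subsite contributes its ordinal pattern score (A=0, B=1, C=2). Three
composites are formed per patient:

* Overall Score     — sum of all seven subsite scores (0-14);
* Partial Score B   — sum restricted to subsites scored 1, i.e. the count
                      of Pattern-B subsites (0-7);
* Partial Score C   — sum restricted to subsites scored 2, i.e. twice the
                      count of Pattern-C subsites (0-14, always even).

By construction ``overall = partial_b + partial_c`` for every patient.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

from .cohort import Cohort, PatientRecord, Pattern

__all__ = ["ScoreTriple", "ScoreTable", "pattern_to_score", "compute_patient_scores", "score_cohort"]


def pattern_to_score(p: Pattern) -> int:
    """Ordinal score of a pattern: A=0, B=1, C=2."""
    return p.score


@dataclass(frozen=True)
class ScoreTriple:
    overall: int
    partial_b: int
    partial_c: int

    def __post_init__(self) -> None:
        if self.overall != self.partial_b + self.partial_c:
            raise ValueError("overall must equal partial_b + partial_c")
        if self.partial_c % 2 != 0:
            raise ValueError("partial_c must be even")
        if not (0 <= self.partial_b <= 7 and 0 <= self.partial_c <= 14):
            raise ValueError("score out of range")


@dataclass
class ScoreTable:
    """Per-patient score triples, one row per cohort record, order preserved."""

    rows: list[tuple[str, ScoreTriple, int]]

    @property
    def overall(self) -> list[int]:
        return [t.overall for _, t, _ in self.rows]

    @property
    def partial_b(self) -> list[int]:
        return [t.partial_b for _, t, _ in self.rows]

    @property
    def partial_c(self) -> list[int]:
        return [t.partial_c for _, t, _ in self.rows]

    @property
    def histology(self) -> list[int]:
        return [h for _, _, h in self.rows]

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(
            ["patient_id", "overall_score", "partial_score_pattern_b",
             "partial_score_pattern_c", "histology"]
        )
        for pid, t, h in self.rows:
            w.writerow([pid, t.overall, t.partial_b, t.partial_c, h])
        return buf.getvalue()


def compute_patient_scores(record: PatientRecord) -> ScoreTriple:
    """Sum the seven subsite scores into the three composites."""
    scores = [p.score for p in record.pattern_tuple()]
    partial_b = sum(s for s in scores if s == 1)
    partial_c = sum(s for s in scores if s == 2)
    return ScoreTriple(overall=sum(scores), partial_b=partial_b, partial_c=partial_c)


def score_cohort(cohort: Cohort) -> ScoreTable:
    """Row-wise scoring of a cohort; row order matches the cohort."""
    cohort.require_nonempty()
    return ScoreTable(
        [(r.patient_id, compute_patient_scores(r), r.histology) for r in cohort]
    )
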