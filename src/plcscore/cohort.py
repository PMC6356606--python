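"""Cohort data model and CSV I/O for posterior-laryngeal-compartment pattern tables.

A cohort is a list of patients, each carrying one MR signal-pattern code
(A/B/C, equivalently 0/1/2) for each of the seven systematically assessed
subsites of the posterior laryngeal compartment (PLC), plus a binary
histological reference standard (1 = neoplastic infiltration of the
PLC / cricoarytenoid unit, 0 = no infiltration).

The published 17-patient reference table ships with the package and is
available through :func:`load_table2_fixture`.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

__all__ = [
    "Subsite",
    "Pattern",
    "PatientRecord",
    "Cohort",
    "CohortError",
    "parse_cohort",
    "write_cohort",
    "load_table2_fixture",
]


class CohortError(ValueError):
    """Invalid cohort input (malformed cell, missing column, duplicate id...)."""


class Subsite(enum.Enum):
    """The seven assessed PLC subsites, in canonical column order.

    Order matters: it is the column order used in the cohort CSV schema
    (posterior vocal muscle, posterior paraglottic space, inferior
    paraglottic space, arytenoid cartilage, cricoid lamina, lateral
    cricoarytenoid muscle, cricothyroid muscle).
    """

    POST_VM = "post_vm"
    POST_PGS = "post_pgs"
    INF_PGS = "inf_pgs"
    ARY = "ary"
    CRIC_LAM = "cric_lam"
    LCAM = "lcam"
    CTM = "ctm"

    @property
    def column(self) -> str:
        """CSV column name for this subsite."""
        return self.value


class Pattern(enum.Enum):
    """MR signal pattern of one subsite.

    A: normal signal in all sequences.
    B: T2 hyperintensity without diffusion restriction (edema/inflammation).
    C: intermediate T2 signal with diffusion restriction (tumor-like tissue).

    Each pattern carries a fixed ordinal score: A=0, B=1, C=2.
    """

    A = 0
    B = 1
    C = 2

    @property
    def score(self) -> int:
        return self.value

    @classmethod
    def from_cell(cls, cell: str) -> "Pattern":
        """Parse a CSV cell: letters A/B/C (any case) or digits 0/1/2."""
        token = cell.strip().upper()
        if token in ("A", "B", "C"):
            return cls[token]
        if token in ("0", "1", "2"):
            return cls(int(token))
        raise CohortError(f"invalid pattern cell {cell!r}: expected A/B/C or 0/1/2")


@dataclass(frozen=True)
class PatientRecord:
    """One patient: id, the seven subsite patterns, and the histology label."""

    patient_id: str
    patterns: dict[Subsite, Pattern]
    histology: int

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortError("patient_id must be a non-empty string")
        missing = [s.column for s in Subsite if s not in self.patterns]
        if missing:
            raise CohortError(
                f"patient {self.patient_id!r}: missing subsite pattern(s): {missing}"
            )
        extra = [k for k in self.patterns if not isinstance(k, Subsite)]
        if extra:
            raise CohortError(f"patient {self.patient_id!r}: unknown subsites {extra}")
        if self.histology not in (0, 1):
            raise CohortError(
                f"patient {self.patient_id!r}: histology must be 0 or 1, "
                f"got {self.histology!r}"
            )

    def pattern_tuple(self) -> tuple[Pattern, ...]:
        """Patterns in canonical subsite order."""
        return tuple(self.patterns[s] for s in Subsite)


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.patient_id in seen:
                raise CohortError(f"duplicate patient_id {r.patient_id!r}")
            seen.add(r.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def get(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    @property
    def histology(self) -> list[int]:
        return [r.histology for r in self.records]

    def require_nonempty(self) -> None:
        if not self.records:
            raise CohortError("cohort is empty; analysis requires at least one record")


_COLUMNS = ["patient_id", *[s.column for s in Subsite], "histology"]


def parse_cohort(source: str | io.TextIOBase | Iterable[str]) -> Cohort:
    """Parse a cohort from CSV text or a text stream.

    Expected header: ``patient_id, post_vm, post_pgs, inf_pgs, ary,
    cric_lam, lcam, ctm, histology`` (case-insensitive, any column order).
    Pattern cells accept letters A/B/C or digits 0/1/2; histology must be
    0 or 1. All validation errors carry row/column context.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    reader = csv.reader(source)
    try:
        header = next(reader)
    except StopIteration:
        raise CohortError("empty input: no header row") from None
    colmap = {name.strip().lower(): i for i, name in enumerate(header)}
    missing = [c for c in _COLUMNS if c not in colmap]
    if missing:
        raise CohortError(f"missing required column(s): {missing}")

    records: list[PatientRecord] = []
    for rownum, row in enumerate(reader, start=2):
        if not row or all(not cell.strip() for cell in row):
            continue  # ignore blank lines
        if len(row) < len(header):
            raise CohortError(f"row {rownum}: expected {len(header)} cells, got {len(row)}")
        pid = row[colmap["patient_id"]].strip()
        if not pid:
            raise CohortError(f"row {rownum}: empty patient_id")
        patterns: dict[Subsite, Pattern] = {}
        for s in Subsite:
            cell = row[colmap[s.column]]
            try:
                patterns[s] = Pattern.from_cell(cell)
            except CohortError as e:
                raise CohortError(f"row {rownum}, column {s.column!r}: {e}") from None
        hist_cell = row[colmap["histology"]].strip()
        if hist_cell not in ("0", "1"):
            raise CohortError(
                f"row {rownum}, column 'histology': expected 0 or 1, got {hist_cell!r}"
            )
        records.append(PatientRecord(pid, patterns, int(hist_cell)))
    return Cohort(records)


def write_cohort(cohort: Cohort) -> str:
    """Serialize a cohort to CSV text. Pattern cells are written as digits.

    Round-trips: ``parse_cohort(write_cohort(c))`` reproduces ``c``
    field-for-field.
    """
    cohort.require_nonempty()
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_COLUMNS)
    for r in cohort:
        writer.writerow(
            [r.patient_id, *[str(r.patterns[s].score) for s in Subsite], str(r.histology)]
        )
    return buf.getvalue()


def load_table2_fixture() -> Cohort:
    """Load the packaged 17-patient reference cohort.

    Patient ids "1".."17"; 8 histology-positive, 9 negative.
    """
    text = resources.files("plcscore.data").joinpath("table2.csv").read_text("utf-8")
    return parse_cohort(text)
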