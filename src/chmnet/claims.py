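"""Claims data model and pharmacoepidemiologic cohort filtering.

One row of a claims table is one dispensed Chinese herbal medicine (CHM)
item at one ambulatory visit.  Visits are reconstructed from rows, an
index population is identified (women ever diagnosed with endometriosis
by a gynecologist), and an inclusion/exclusion cascade reduces raw visits
to analyzable CHM prescriptions:

1. visit made by an index-eligible patient;
2. patient age at the visit within [age_min, age_max] completed years
   (bounds inclusive);
3. first-listed (primary) diagnosis matches a configured ICD-9-CM prefix;
4. no excluded therapy type (acupuncture, moxibustion, manual therapy)
   dispensed at the visit;
5. at least one CHM item on the visit.

The set of distinct item codes of one retained visit is one transaction,
the unit over which support/prevalence is defined downstream.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CHMItem",
    "VisitRecord",
    "CohortConfig",
    "AttritionReport",
    "ClaimsDialect",
    "Transaction",
    "ClaimsFormatError",
    "read_claims",
    "write_claims",
    "index_patients",
    "filter_cohort",
    "to_transactions",
    "write_transactions",
    "read_transactions",
    "age_in_completed_years",
]

HF = "HF"
SH = "SH"

THERAPY_TYPES = ("chm", "acupuncture", "moxibustion", "manual")


class ClaimsFormatError(ValueError):
    """Raised when a claims table is structurally invalid."""


@dataclass(frozen=True)
class CHMItem:
    """A dispensed CHM product: herbal formula (HF) or single herb (SH)."""

    code: str
    name: str
    kind: str  # "HF" or "SH"
    dose_g_per_day: float
    duration_days: float

    def __post_init__(self) -> None:
        if self.kind not in (HF, SH):
            raise ValueError(f"kind must be 'HF' or 'SH', got {self.kind!r}")
        if self.dose_g_per_day < 0 or self.duration_days < 0:
            raise ValueError("dose and duration must be nonnegative")


@dataclass
class VisitRecord:
    """One ambulatory visit with its diagnoses, therapies and CHM items."""

    patient_id: str
    visit_id: str
    visit_date: date
    patient_birth_date: date
    provider_specialty: str  # gynecology | tcm | other
    diagnosis_codes: list[str]  # position 0 = primary reason of the visit
    therapy_types: frozenset[str]
    items: list[CHMItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.visit_date < self.patient_birth_date:
            raise ValueError(
                f"visit {self.visit_id}: visit_date precedes birth date"
            )
        self.therapy_types = frozenset(self.therapy_types)

    @property
    def item_codes(self) -> frozenset[str]:
        return frozenset(it.code for it in self.items)


@dataclass(frozen=True)
class CohortConfig:
    """Inclusion/exclusion parameters of the cohort cascade.

    The diagnosis of interest is matched by ICD-9-CM code *prefix*
    (claims codes carry subdigits, e.g. prefix "617" matches "617.0").
    """

    endometriosis_code_prefixes: tuple[str, ...] = ("617",)
    age_min_years: int = 20
    age_max_years: int = 50
    require_primary_diagnosis: bool = True
    require_gynecologist_index_diagnosis: bool = True
    excluded_therapy_types: frozenset[str] = frozenset(
        {"acupuncture", "moxibustion", "manual"}
    )
    chm_only: bool = True

    def __post_init__(self) -> None:
        if not self.endometriosis_code_prefixes:
            raise ValueError("at least one diagnosis code prefix is required")
        if self.age_min_years > self.age_max_years:
            raise ValueError("age_min_years must be <= age_max_years")
        object.__setattr__(
            self, "excluded_therapy_types", frozenset(self.excluded_therapy_types)
        )
        object.__setattr__(
            self,
            "endometriosis_code_prefixes",
            tuple(self.endometriosis_code_prefixes),
        )

    def matches_diagnosis(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.endometriosis_code_prefixes)


@dataclass(frozen=True)
class AttritionReport:
    """Visit counts at each step of the inclusion/exclusion cascade."""

    total_visits: int
    visits_by_eligible_patients: int
    age_in_range: int
    primary_diagnosis_match: int
    therapy_exclusions_passed: int
    chm_visits_retained: int

    STEPS = (
        "total_visits",
        "visits_by_eligible_patients",
        "age_in_range",
        "primary_diagnosis_match",
        "therapy_exclusions_passed",
        "chm_visits_retained",
    )

    def counts(self) -> list[int]:
        return [getattr(self, s) for s in self.STEPS]

    def is_monotone(self) -> bool:
        c = self.counts()
        return all(a >= b for a, b in zip(c, c[1:]))

    def to_dict(self) -> dict[str, int]:
        return {s: getattr(self, s) for s in self.STEPS}

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_text(self, path: str | Path) -> None:
        lines = [f"{s}\t{getattr(self, s)}" for s in self.STEPS]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class Transaction:
    """The set of distinct CHM codes dispensed at one retained visit."""

    visit_id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", frozenset(self.items))


@dataclass(frozen=True)
class ClaimsDialect:
    """Delimiter and column-name mapping of a claims table."""

    delimiter: str = ","
    list_separator: str = ";"  # within-cell separator for diagnosis/therapy lists
    columns: dict[str, str] = field(
        default_factory=lambda: {
            "patient_id": "patient_id",
            "visit_id": "visit_id",
            "visit_date": "visit_date",
            "birth_date": "birth_date",
            "specialty": "specialty",
            "diagnoses": "diagnoses",
            "therapies": "therapies",
            "item_code": "item_code",
            "item_name": "item_name",
            "item_kind": "item_kind",
            "dose_g_per_day": "dose_g_per_day",
            "duration_days": "duration_days",
        }
    )


def age_in_completed_years(birth: date, at: date) -> int:
    """Age in completed years at a given date (claims convention)."""
    years = at.year - birth.year
    if (at.month, at.day) < (birth.month, birth.day):
        years -= 1
    return years


def _parse_date(text: str, row_index: int, column: str) -> date:
    try:
        return date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ClaimsFormatError(
            f"row {row_index}: unparseable date {text!r} in column {column!r}"
        ) from exc


def read_claims(
    path: str | Path, dialect: ClaimsDialect | None = None
) -> list[VisitRecord]:
    """Read a delimited claims table into visit records.

    One output record per distinct ``(patient_id, visit_id)``.  Rows of the
    same visit carrying an identical item code are merged: doses summed,
    the maximum duration kept (split-dispense convention).  Rows with an
    empty item code contribute a visit with no items.  Output order — and
    everything downstream — is independent of input row order.
    """
    dialect = dialect or ClaimsDialect()
    cols = dialect.columns
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        for mandatory in cols.values():
            if mandatory not in header:
                raise ClaimsFormatError(f"missing mandatory column {mandatory!r}")
        visits: dict[tuple[str, str], VisitRecord] = {}
        item_acc: dict[tuple[str, str], dict[str, CHMItem]] = {}
        for i, row in enumerate(reader):
            pid = row[cols["patient_id"]].strip()
            vid = row[cols["visit_id"]].strip()
            key = (pid, vid)
            if key not in visits:
                diagnoses = [
                    d.strip()
                    for d in row[cols["diagnoses"]].split(dialect.list_separator)
                    if d.strip()
                ]
                therapies = frozenset(
                    t.strip()
                    for t in row[cols["therapies"]].split(dialect.list_separator)
                    if t.strip()
                )
                visits[key] = VisitRecord(
                    patient_id=pid,
                    visit_id=vid,
                    visit_date=_parse_date(row[cols["visit_date"]], i, "visit_date"),
                    patient_birth_date=_parse_date(
                        row[cols["birth_date"]], i, "birth_date"
                    ),
                    provider_specialty=row[cols["specialty"]].strip(),
                    diagnosis_codes=diagnoses,
                    therapy_types=therapies,
                    items=[],
                )
                item_acc[key] = {}
            code = row[cols["item_code"]].strip()
            if not code:
                continue
            try:
                dose = float(row[cols["dose_g_per_day"]])
                duration = float(row[cols["duration_days"]])
            except ValueError as exc:
                raise ClaimsFormatError(
                    f"row {i}: non-numeric dose/duration for item {code!r}"
                ) from exc
            item = CHMItem(
                code=code,
                name=row[cols["item_name"]].strip(),
                kind=row[cols["item_kind"]].strip(),
                dose_g_per_day=dose,
                duration_days=duration,
            )
            acc = item_acc[key]
            if code in acc:
                prev = acc[code]
                acc[code] = replace(
                    prev,
                    dose_g_per_day=prev.dose_g_per_day + item.dose_g_per_day,
                    duration_days=max(prev.duration_days, item.duration_days),
                )
            else:
                acc[code] = item
        out = []
        for key in sorted(visits):
            v = visits[key]
            v.items = [item_acc[key][c] for c in sorted(item_acc[key])]
            out.append(v)
        return out


def write_claims(
    visits: Iterable[VisitRecord],
    path: str | Path,
    dialect: ClaimsDialect | None = None,
) -> None:
    """Write visits back to the one-row-per-(visit, item) delimited layout."""
    dialect = dialect or ClaimsDialect()
    cols = dialect.columns
    fieldnames = list(cols.values())
    sep = dialect.list_separator
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter=dialect.delimiter)
        writer.writeheader()
        for v in visits:
            base = {
                cols["patient_id"]: v.patient_id,
                cols["visit_id"]: v.visit_id,
                cols["visit_date"]: v.visit_date.isoformat(),
                cols["birth_date"]: v.patient_birth_date.isoformat(),
                cols["specialty"]: v.provider_specialty,
                cols["diagnoses"]: sep.join(v.diagnosis_codes),
                cols["therapies"]: sep.join(sorted(v.therapy_types)),
            }
            rows = v.items or [None]
            for item in rows:
                row = dict(base)
                if item is None:
                    row.update(
                        {
                            cols["item_code"]: "",
                            cols["item_name"]: "",
                            cols["item_kind"]: SH,
                            cols["dose_g_per_day"]: "0",
                            cols["duration_days"]: "0",
                        }
                    )
                else:
                    row.update(
                        {
                            cols["item_code"]: item.code,
                            cols["item_name"]: item.name,
                            cols["item_kind"]: item.kind,
                            cols["dose_g_per_day"]: repr(item.dose_g_per_day),
                            cols["duration_days"]: repr(item.duration_days),
                        }
                    )
                writer.writerow(row)


def index_patients(
    visits: Sequence[VisitRecord], config: CohortConfig
) -> set[str]:
    """Patients with >=1 qualifying index diagnosis.

    A qualifying index visit carries the diagnosis of interest (any listed
    position) and, when ``require_gynecologist_index_diagnosis`` is set,
    was made to a gynecologist.
    """
    eligible: set[str] = set()
    for v in visits:
        if config.require_gynecologist_index_diagnosis and (
            v.provider_specialty != "gynecology"
        ):
            continue
        if any(config.matches_diagnosis(d) for d in v.diagnosis_codes):
            eligible.add(v.patient_id)
    return eligible


def filter_cohort(
    visits: Sequence[VisitRecord],
    eligible: set[str],
    config: CohortConfig,
) -> tuple[list[VisitRecord], AttritionReport]:
    """Apply the inclusion/exclusion cascade; count every step.

    Steps are applied in a fixed order so the attrition counts are
    monotone non-increasing by construction.
    """
    step0 = sorted(visits, key=lambda v: (v.patient_id, v.visit_id))
    step1 = [v for v in step0 if v.patient_id in eligible]
    step2 = [
        v
        for v in step1
        if config.age_min_years
        <= age_in_completed_years(v.patient_birth_date, v.visit_date)
        <= config.age_max_years
    ]
    if config.require_primary_diagnosis:
        step3 = [
            v
            for v in step2
            if v.diagnosis_codes and config.matches_diagnosis(v.diagnosis_codes[0])
        ]
    else:
        step3 = [
            v for v in step2 if any(config.matches_diagnosis(d) for d in v.diagnosis_codes)
        ]
    step4 = [
        v for v in step3 if not (v.therapy_types & config.excluded_therapy_types)
    ]
    step5 = [v for v in step4 if v.items] if config.chm_only else list(step4)
    report = AttritionReport(
        total_visits=len(step0),
        visits_by_eligible_patients=len(step1),
        age_in_range=len(step2),
        primary_diagnosis_match=len(step3),
        therapy_exclusions_passed=len(step4),
        chm_visits_retained=len(step5),
    )
    return step5, report


def to_transactions(retained: Sequence[VisitRecord]) -> list[Transaction]:
    """One transaction (set of distinct CHM codes) per retained visit."""
    return [Transaction(v.visit_id, v.item_codes) for v in retained]


def write_transactions(
    transactions: Iterable[Transaction], path: str | Path
) -> None:
    """One line per visit: ``visit_id<TAB>code;code;...`` (codes sorted)."""
    with Path(path).open("w") as fh:
        for t in transactions:
            fh.write(f"{t.visit_id}\t{';'.join(sorted(t.items))}\n")


def read_transactions(path: str | Path) -> list[Transaction]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        vid, _, rest = line.partition("\t")
        items = frozenset(c for c in rest.split(";") if c)
        out.append(Transaction(vid, items))
    return out
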