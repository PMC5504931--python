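from datetime import date

import pytest

from chmnet.claims import CHMItem, CohortConfig, Transaction, VisitRecord


def make_item(code: str, kind: str = "SH", dose: float = 1.0, dur: float = 10.0) -> CHMItem:
    return CHMItem(code=code, name=code.title(), kind=kind, dose_g_per_day=dose, duration_days=dur)


def make_visit(
    patient: str = "P1",
    visit: str = "V1",
    vdate: date = date(2005, 6, 1),
    birth: date = date(1975, 1, 15),
    specialty: str = "tcm",
    diagnoses: tuple[str, ...] = ("617.0",),
    therapies: frozenset[str] = frozenset({"chm"}),
    items: tuple[str, ...] = ("A", "B"),
) -> VisitRecord:
    return VisitRecord(
        patient_id=patient,
        visit_id=visit,
        visit_date=vdate,
        patient_birth_date=birth,
        provider_specialty=specialty,
        diagnosis_codes=list(diagnoses),
        therapy_types=frozenset(therapies),
        items=[make_item(c) for c in items],
    )


def tx(*itemsets: str) -> list[Transaction]:
    """Transactions from strings: tx("AB", "A", "C") -> three visits."""
    return [
        Transaction(visit_id=f"V{i}", items=frozenset(s)) for i, s in enumerate(itemsets)
    ]


@pytest.fixture
def cohort_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture
def five_patients() -> list[VisitRecord]:
    """Two patients with gynecologist-confirmed disease, three without."""
    return [
        make_visit("P1", "V1", specialty="gynecology", diagnoses=("617.0",)),
        make_visit("P1", "V2", specialty="tcm", diagnoses=("617.0",)),
        make_visit("P2", "V3", specialty="gynecology", diagnoses=("617.3", "780.1")),
        make_visit("P3", "V4", specialty="gynecology", diagnoses=("780.1",)),
        make_visit("P4", "V5", specialty="tcm", diagnoses=("617.0",)),  # not gyn
        make_visit("P5", "V6", specialty="other", diagnoses=("460",)),
    ]
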