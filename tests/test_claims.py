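import random
from datetime import date
from pathlib import Path

import pytest

from chmnet.claims import (
    ClaimsDialect,
    ClaimsFormatError,
    CohortConfig,
    age_in_completed_years,
    filter_cohort,
    index_patients,
    read_claims,
    read_transactions,
    to_transactions,
    write_claims,
    write_transactions,
)
from .conftest import make_visit

HEADER = (
    "patient_id,visit_id,visit_date,birth_date,specialty,diagnoses,"
    "therapies,item_code,item_name,item_kind,dose_g_per_day,duration_days"
)


def _write(tmp_path: Path, rows: list[str]) -> Path:
    p = tmp_path / "claims.csv"
    p.write_text("\n".join([HEADER] + rows) + "\n")
    return p


ROW = "P1,V1,2005-06-01,1980-01-15,tcm,617.0,chm,{code},{name},SH,{dose},{dur}"


class TestReadClaims:
    def test_header_only_gives_empty_list(self, tmp_path):
        assert read_claims(_write(tmp_path, [])) == []

    def test_rows_sharing_visit_become_one_record(self, tmp_path):
        rows = [
            ROW.format(code=c, name=c, dose=1.0, dur=10) for c in ("A", "B", "C")
        ]
        visits = read_claims(_write(tmp_path, rows))
        assert len(visits) == 1
        assert visits[0].item_codes == {"A", "B", "C"}

    def test_duplicate_item_rows_merge_doses_and_keep_max_duration(self, tmp_path):
        rows = [
            ROW.format(code="A", name="A", dose=2.0, dur=7),
            ROW.format(code="A", name="A", dose=2.0, dur=14),
        ]
        (visit,) = read_claims(_write(tmp_path, rows))
        (item,) = visit.items
        assert item.dose_g_per_day == pytest.approx(4.0)
        assert item.duration_days == pytest.approx(14.0)

    def test_missing_column_error_names_the_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(HEADER.replace("item_kind,", "") + "\nx\n")
        with pytest.raises(ClaimsFormatError, match="item_kind"):
            read_claims(p)

    def test_unparseable_date_reports_row_index(self, tmp_path):
        rows = [
            ROW.format(code="A", name="A", dose=1, dur=1),
            "P2,V2,not-a-date,1980-01-15,tcm,617.0,chm,B,B,SH,1,1",
        ]
        with pytest.raises(ClaimsFormatError, match="row 1"):
            read_claims(_write(tmp_path, rows))

    def test_row_order_never_affects_output(self, tmp_path):
        rows = [
            f"P{p},V{p}{v},2005-06-0{v},1980-01-15,tcm,617.0,chm,{c},{c},SH,1.5,10"
            for p in (1, 2, 3)
            for v in (1, 2)
            for c in ("A", "B", "X")
        ]
        base = read_claims(_write(tmp_path, rows))
        shuffled = rows[:]
        random.Random(7).shuffle(shuffled)
        assert read_claims(_write(tmp_path, shuffled)) == base

    def test_round_trip_through_writer(self, tmp_path):
        visits = [
            make_visit("P1", "V1", items=("A", "B")),
            make_visit("P2", "V2", items=("C",), therapies=frozenset({"chm", "manual"})),
        ]
        p = tmp_path / "out.csv"
        write_claims(visits, p)
        assert read_claims(p) == sorted(visits, key=lambda v: v.patient_id)

    def test_custom_dialect(self, tmp_path):
        dialect = ClaimsDialect(delimiter="\t")
        p = tmp_path / "claims.tsv"
        write_claims([make_visit()], p, dialect)
        assert read_claims(p, dialect)[0].item_codes == {"A", "B"}


class TestIndexPatients:
    def test_no_gynecology_visits_gives_empty_set(self, cohort_config):
        visits = [make_visit("P1", "V1", specialty="tcm")]
        assert index_patients(visits, cohort_config) == set()

    def test_two_of_five_patients_qualify(self, five_patients, cohort_config):
        assert index_patients(five_patients, cohort_config) == {"P1", "P2"}

    def test_matching_code_at_non_gyn_visit_is_excluded(self, five_patients, cohort_config):
        # P4 carries the code but only at a TCM visit
        assert "P4" not in index_patients(five_patients, cohort_config)
        relaxed = CohortConfig(require_gynecologist_index_diagnosis=False)
        assert "P4" in index_patients(five_patients, relaxed)


class TestFilterCohort:
    def test_secondary_position_diagnosis_is_excluded(self, cohort_config):
        visits = [make_visit(diagnoses=("780.1", "617.0"), specialty="gynecology")]
        retained, report = filter_cohort(visits, {"P1"}, cohort_config)
        assert retained == []
        assert report.primary_diagnosis_match == 0
        assert report.age_in_range == 1

    def test_excluded_therapy_drops_visit(self, cohort_config):
        visits = [make_visit(therapies=frozenset({"chm", "acupuncture"}))]
        retained, report = filter_cohort(visits, {"P1"}, cohort_config)
        assert retained == []
        assert report.therapy_exclusions_passed == 0

    @pytest.mark.parametrize("age,kept", [(19, False), (20, True), (50, True), (51, False)])
    def test_age_bounds_inclusive(self, cohort_config, age, kept):
        visits = [
            make_visit(vdate=date(2000 + age, 6, 1), birth=date(2000, 1, 1))
        ]
        retained, _ = filter_cohort(visits, {"P1"}, cohort_config)
        assert bool(retained) is kept

    def test_attrition_is_monotone_and_idempotent(self, five_patients, cohort_config):
        eligible = index_patients(five_patients, cohort_config)
        retained, report = filter_cohort(five_patients, eligible, cohort_config)
        assert report.is_monotone()
        again, report2 = filter_cohort(retained, eligible, cohort_config)
        assert again == retained
        assert report2.chm_visits_retained == len(retained)

    def test_empty_visit_dropped_when_chm_only(self, cohort_config):
        visits = [make_visit(items=())]
        retained, report = filter_cohort(visits, {"P1"}, cohort_config)
        assert retained == []
        assert report.therapy_exclusions_passed == 1
        keep = CohortConfig(chm_only=False)
        retained, _ = filter_cohort(visits, {"P1"}, keep)
        assert len(retained) == 1


class TestTransactions:
    def test_set_semantics_and_bijection(self):
        visits = [
            make_visit("P1", "V1", items=("A", "B")),
            make_visit("P1", "V2", items=("B",)),
            make_visit("P2", "V3", items=("C", "A")),
            make_visit("P2", "V4", items=("B", "C", "A")),
        ]
        txs = to_transactions(visits)
        assert len(txs) == 4
        assert [set(t.items) for t in txs] == [
            {"A", "B"},
            {"B"},
            {"A", "C"},
            {"A", "B", "C"},
        ]

    def test_file_round_trip(self, tmp_path):
        txs = to_transactions([make_visit(items=("B", "A"))])
        p = tmp_path / "tx.tsv"
        write_transactions(txs, p)
        assert p.read_text() == "V1\tA;B\n"
        assert read_transactions(p) == txs


def test_age_in_completed_years_handles_birthday_boundary():
    assert age_in_completed_years(date(1980, 6, 2), date(2000, 6, 1)) == 19
    assert age_in_completed_years(date(1980, 6, 1), date(2000, 6, 1)) == 20
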