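"""Cross-source coherence: baby DOB reconciliation, congenital conditions,
mother YOB and sex, hysterectomy ordering, discharge/death orderings."""

import pandas as pd
import pytest

from linkclean.cross_source import (check_admission_after_discharge,
                                    check_birth_after_hysterectomy,
                                    check_congenital_consistency,
                                    check_dob_after_discharge,
                                    check_mother_sex, check_mother_yob,
                                    check_service_after_death,
                                    reconcile_baby_dob)
from linkclean.model import FlagLedger, ReviewQueue

from conftest import (death_row, encounter_row, make_table, perinatal_row)


def _dob_fixture(perinatal_dob, patient_dob, *, window=("2010-03-04",
                                                        "2010-03-08")):
    per = make_table("perinatal", [
        perinatal_row("R1", "M1", "B1", perinatal_dob)])
    enc = make_table("encounters", [
        encounter_row("E1", "M1", window[0], window[1], dob="1980-05-01",
                      is_delivery=1),
        encounter_row("E2", "B1", patient_dob, "2010-03-09", role="baby",
                      dob=patient_dob, age=0),
    ])
    return per, enc


def test_alternative_dob_accepted_from_delivery_window():
    # day/month transposition: recorded 2010-05-03, true 2010-03-05
    per, enc = _dob_fixture("2010-05-03", "2010-03-05")
    ledger, review = FlagLedger(), ReviewQueue()
    recs = reconcile_baby_dob(per, enc, ledger, review)
    assert recs[0].accepted_alternative == pd.Timestamp("2010-03-05")
    assert [(c.record_id, c.field, str(c.new_value)[:10])
            for c in ledger.corrections[:1]] == [("R1", "baby_dob",
                                                  "2010-03-05")]


def test_patient_dob_outside_window_not_accepted():
    per, enc = _dob_fixture("2010-05-03", "2010-03-20")
    ledger, review = FlagLedger(), ReviewQueue()
    recs = reconcile_baby_dob(per, enc, ledger, review)
    assert recs[0].accepted_alternative is None


def test_age_corrected_when_dates_share_month_and_day():
    # updated DOB 2010-05-03 vs patient DOB 2011-05-03
    per = make_table("perinatal", [
        perinatal_row("R1", "M1", "B1", "2010-05-03")])
    enc = make_table("encounters", [
        encounter_row("E1", "B1", "2011-06-01", "2011-06-03", role="baby",
                      dob="2010-05-03", age=1),
        encounter_row("E2", "B1", "2011-07-01", "2011-07-03", role="baby",
                      dob="2011-05-03", age=0),
    ])
    ledger, review = FlagLedger(), ReviewQueue()
    reconcile_baby_dob(per, enc, ledger, review)
    assert [(c.record_id, c.field, c.step_id) for c in ledger.corrections] \
        == [("E2", "patient_age", "S9.4")]
    assert not ledger.entries


def test_deletion_when_dates_far_apart_with_no_shared_component():
    # 241 days apart, no shared (month,year)/(month,day)/(day,year) pair
    per = make_table("perinatal", [
        perinatal_row("R1", "M1", "B1", "2010-01-01")])
    enc = make_table("encounters", [
        encounter_row("E1", "B1", "2010-02-01", "2010-02-02", role="baby",
                      dob="2010-01-01", age=0),
        encounter_row("E2", "B1", "2010-09-01", "2010-09-02", role="baby",
                      dob="2010-08-30", age=0),
    ])
    ledger, review = FlagLedger(), ReviewQueue()
    reconcile_baby_dob(per, enc, ledger, review)
    assert ledger.flagged_records(["deletion"]) == {"E2"}
    assert ledger.entries[0].step_id == "S9.4"


def test_exactly_140_days_resolves_to_deletion():
    # gap of exactly 20 weeks is neither "less than" nor "more than"
    d = pd.Timestamp("2010-01-05")
    far = d + pd.Timedelta(days=140)
    assert far.day != d.day and far.month != d.month
    per = make_table("perinatal", [
        perinatal_row("R1", "M1", "B1", d.strftime("%Y-%m-%d"))])
    enc = make_table("encounters", [
        encounter_row("E1", "B1", "2010-02-01", "2010-02-02", role="baby",
                      dob=d.strftime("%Y-%m-%d"), age=0),
        encounter_row("E2", "B1", "2010-06-01", "2010-06-02", role="baby",
                      dob=far.strftime("%Y-%m-%d"), age=0),
    ])
    ledger, review = FlagLedger(), ReviewQueue()
    reconcile_baby_dob(per, enc, ledger, review)
    assert ledger.flagged_records(["deletion"]) == {"E2"}


class TestCongenital:
    per = staticmethod(lambda bw=3400: make_table("perinatal", [
        perinatal_row("R1", "M1", "B1", "2005-01-01", bw=3400),
        perinatal_row("R2", "M1", "B2", "2007-06-01", parity=1, bw=3600),
    ]))

    def test_single_mismatch_no_action(self):
        cong = make_table("congenital", [
            {"record_id": "C1", "baby_ppn": "B1", "baby_dob": "2005-02-01",
             "birthweight": 3400}])
        ledger, review = FlagLedger(), ReviewQueue()
        check_congenital_consistency(self.per(), cong, ledger, review)
        assert not ledger.entries and not review.items

    def test_sibling_dob_match_excludes_mother(self):
        cong = make_table("congenital", [
            {"record_id": "C1", "baby_ppn": "B1", "baby_dob": "2007-06-01",
             "birthweight": 2900}])
        ledger, review = FlagLedger(), ReviewQueue()
        check_congenital_consistency(self.per(), cong, ledger, review)
        assert ledger.excluded_persons() == {"M1"}
        assert ledger.entries[0].step_id == "S10.3"

    def test_double_mismatch_without_sibling_goes_to_review(self):
        cong = make_table("congenital", [
            {"record_id": "C1", "baby_ppn": "B1", "baby_dob": "2005-03-03",
             "birthweight": 2900}])
        ledger, review = FlagLedger(), ReviewQueue()
        check_congenital_consistency(self.per(), cong, ledger, review)
        assert not ledger.entries
        assert review.items[0]["step_id"] == "S10.3"


def _yob_fixture(yobs):
    # perinatal data from two anchor mothers define the valid range 1941-1999
    rows = [perinatal_row("RA", "MA", "BA", "2005-01-01", mother_yob=1941),
            perinatal_row("RB", "MB", "BB", "2005-01-01", mother_yob=1999),
            perinatal_row("R1", "M1", "B1", "2005-01-01", mother_yob=yobs[0])]
    enc_rows = [encounter_row(f"E{i}", "M1", "2006-01-01", "2006-01-02",
                              dob=f"{y}-03-01")
                for i, y in enumerate(yobs[1:], start=1)]
    return make_table("perinatal", rows), make_table("encounters", enc_rows)


def test_single_out_of_range_yob_tolerated():
    per, enc = _yob_fixture([1975, 1975, 1930])
    ledger = FlagLedger()
    assert check_mother_yob(per, enc, ledger) == []


def test_two_out_of_range_yobs_excluded():
    per, enc = _yob_fixture([1975, 1930, 1930])
    ledger = FlagLedger()
    assert check_mother_yob(per, enc, ledger) == ["M1"]
    assert ledger.exclusion_step("M1") == "S11.4"


def test_more_than_three_distinct_yobs_excluded():
    per, enc = _yob_fixture([1975, 1976, 1977, 1978])
    ledger = FlagLedger()
    assert check_mother_yob(per, enc, ledger) == ["M1"]


def test_invalid_yobs_dropped_before_assessment():
    per, enc = _yob_fixture([1975, 1880, 1880])   # invalid (<1900), dropped
    ledger = FlagLedger()
    assert check_mother_yob(per, enc, ledger) == []


def _sex_fixture(sexes, mobs):
    per = make_table("perinatal", [
        perinatal_row("R1", "M1", "B1", "2005-01-01", mother_yob=1980)])
    enc_rows = [encounter_row(f"E{i}", "M1", "2006-01-01", "2006-01-02",
                              dob="1980-03-01", sex=s, mob=mo)
                for i, (s, mo) in enumerate(zip(sexes, mobs))]
    return per, make_table("encounters", enc_rows)


def test_two_male_records_with_conflicting_month_excluded():
    per, enc = _sex_fixture(["male", "male"], [3, 4])
    ledger = FlagLedger()
    assert check_mother_sex(per, enc, ledger) == ["M1"]
    assert ledger.exclusion_step("M1") == "S12.2"


def test_single_male_record_tolerated():
    per, enc = _sex_fixture(["male", "female"], [3, 4])
    ledger = FlagLedger()
    assert check_mother_sex(per, enc, ledger) == []


def test_male_records_with_consistent_birth_details_tolerated():
    per, enc = _sex_fixture(["male", "male", "male"], [3, 3, 3])
    ledger = FlagLedger()
    assert check_mother_sex(per, enc, ledger) == []


HYST = ["3565300"]


def _hyst_fixture(sep, delivery="2008-03-01"):
    per = make_table("perinatal", [
        perinatal_row("R1", "M1", "B1", delivery)])
    enc = make_table("encounters", [
        encounter_row("E1", "M1", sep, sep, dob="1980-03-01", codes=HYST[0])])
    return per, enc


def test_delivery_after_hysterectomy_excluded():
    per, enc = _hyst_fixture("2007-02-01")
    ledger = FlagLedger()
    assert check_birth_after_hysterectomy(per, enc, HYST, ledger) == ["M1"]
    assert ledger.exclusion_step("M1") == "S13.3"


def test_hysterectomy_after_last_delivery_tolerated():
    per, enc = _hyst_fixture("2009-02-01")
    ledger = FlagLedger()
    assert check_birth_after_hysterectomy(per, enc, HYST, ledger) == []


def test_same_day_separation_and_delivery_not_flagged():
    per, enc = _hyst_fixture("2008-03-01")   # strictly earlier required
    ledger = FlagLedger()
    assert check_birth_after_hysterectomy(per, enc, HYST, ledger) == []


def test_empty_code_list_skips_check():
    per, enc = _hyst_fixture("2007-02-01")
    assert check_birth_after_hysterectomy(per, enc, [], FlagLedger()) == []


def _s14_fixture(updated, sep, patient_dob):
    per = make_table("perinatal", [perinatal_row("R1", "M1", "B1", updated)])
    enc = make_table("encounters", [
        encounter_row("E1", "B1", sep, sep, role="baby", dob=patient_dob,
                      age=0)])
    return per, enc


def test_dob_after_discharge_far_gap_excludes_baby():
    per, enc = _s14_fixture("2010-06-01", "2010-01-15", "2010-01-10")
    ledger = FlagLedger()
    out = check_dob_after_discharge(per, enc, ledger)
    assert out["exclusions"] == ["B1"]
    assert ledger.exclusion_step("B1") == "S14.3"


def test_dob_after_discharge_close_gap_deletes_record():
    per, enc = _s14_fixture("2010-03-01", "2010-01-15", "2010-01-10")
    ledger = FlagLedger()
    out = check_dob_after_discharge(per, enc, ledger)
    assert out["deletions"] == ["E1"]
    assert not ledger.excluded_persons()


def test_dob_before_discharge_untouched():
    per, enc = _s14_fixture("2010-01-01", "2010-01-15", "2010-01-01")
    ledger = FlagLedger()
    out = check_dob_after_discharge(per, enc, ledger)
    assert out == {"exclusions": [], "deletions": []}


def _s15_fixture(death, discharge):
    per = make_table("perinatal", [perinatal_row("R1", "M1", "B1",
                                                 "2008-01-01")])
    enc = make_table("encounters", [
        encounter_row("E1", "M1", discharge, discharge, dob="1980-03-01")])
    deaths = make_table("deaths", [death_row("D1", "M1", death)])
    return per, enc, deaths


def test_discharge_within_three_day_allowance_tolerated():
    per, enc, deaths = _s15_fixture("2010-01-01", "2010-01-03")
    ledger = FlagLedger()
    assert check_service_after_death(per, enc, deaths, ledger) == []
    # boundary: exactly death + 3 days still tolerated
    per, enc, deaths = _s15_fixture("2010-01-01", "2010-01-04")
    assert check_service_after_death(per, enc, deaths, FlagLedger()) == []


def test_discharge_beyond_allowance_excludes():
    per, enc, deaths = _s15_fixture("2010-01-01", "2010-01-10")
    ledger = FlagLedger()
    assert check_service_after_death(per, enc, deaths, ledger) == ["M1"]
    assert ledger.exclusion_step("M1") == "S15.4"


def test_delivery_after_death_excludes():
    per, enc, deaths = _s15_fixture("2007-01-01", "2006-06-01")
    ledger = FlagLedger()
    assert check_service_after_death(per, enc, deaths, ledger) == ["M1"]


def test_admission_after_discharge_deleted_same_day_kept():
    enc = make_table("encounters", [
        encounter_row("E1", "P1", "2010-05-10", "2010-05-08"),
        encounter_row("E2", "P1", "2010-05-08", "2010-05-08"),
        encounter_row("E3", "P2", "2010-05-08", "2010-05-10"),
    ])
    ledger = FlagLedger()
    assert check_admission_after_discharge(enc, ledger) == ["E1"]
    assert ledger.entries[0].step_id == "S16.1"
    assert check_admission_after_discharge(make_table("encounters", []),
                                           FlagLedger()) == []
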