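"""Shared builders and fixtures: tiny hand-built tables plus session-scoped
synthetic cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from linkclean.io import TABLE_COLUMNS, coerce_table
from linkclean.synth import CohortConfig, generate_clean_cohort


def perinatal_row(record_id, mum, baby, dob, *, jur="A", gest=39, bw=3400,
                  parity=0, plurality=1, order=1, mother_yob=1980,
                  mother_age=None, apgar5=9, discharge="home",
                  postcode="2000", country="AU", hospital="H01"):
    if mother_age is None:
        mother_age = int(str(dob)[:4]) - mother_yob
    return {
        "record_id": record_id, "jurisdiction": jur, "mum_ppn": mum,
        "baby_ppn": baby, "baby_dob": dob, "gestational_age": gest,
        "birthweight": bw, "parity": parity, "plurality": plurality,
        "birth_order": order, "mother_yob": mother_yob,
        "mother_age": mother_age, "apgar5": apgar5,
        "discharge_status": discharge, "postcode": postcode,
        "country_of_birth": country, "hospital": hospital,
    }


def encounter_row(record_id, ppn, adm, sep, *, jur="A", role="mother",
                  source="hospital", dob=None, yob=None, age=30,
                  sex="female", mob=None, codes=None, discharge="home",
                  is_delivery=0):
    if dob is not None and yob is None:
        yob = int(str(dob)[:4])
    if dob is not None and mob is None:
        mob = int(str(dob)[5:7])
    return {
        "record_id": record_id, "jurisdiction": jur, "ppn": ppn,
        "role": role, "source": source, "admission_date": adm,
        "separation_date": sep, "patient_dob": dob, "patient_yob": yob,
        "patient_age": age, "patient_sex": sex, "month_of_birth": mob,
        "procedure_codes": codes, "discharge_status": discharge,
        "is_delivery": is_delivery,
    }


def death_row(record_id, ppn, date, *, jur="A", stream="registration"):
    return {"record_id": record_id, "jurisdiction": jur, "ppn": ppn,
            "date_of_death": date, "stream": stream}


def make_table(kind, rows):
    return coerce_table(pd.DataFrame(rows, columns=TABLE_COLUMNS[kind]), kind)


def empty_table(kind):
    return make_table(kind, [])


@pytest.fixture(scope="session")
def small_clean_cohort():
    """A modest clean cohort shared by read-only tests."""
    return generate_clean_cohort(CohortConfig(n_mothers_per_jurisdiction=150,
                                              seed=11))[0]
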