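"""Coherence of dates of birth, years of birth, sex, procedures and event
ordering across perinatal, hospital, emergency-department, death and
congenital-condition tables.

The perinatal baby date of birth is the validated reference item.  When it
disagrees with the patient DOB carried on the baby's other records, the
maternal delivery admission window adjudicates: a patient DOB falling inside
an admission that indicates a birth delivery can replace the perinatal date,
subject to safeguards against sibling mix-ups and new interval/parity
inconsistencies.  Chronologically impossible orderings (a birth after the
mother's hysterectomy, health-service use after death, discharge before
admission) flag persons for exclusion or records for deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta

import pandas as pd

from .model import FlagLedger, ReviewQueue, active_perinatal, active_records
from .perinatal import classify_parity_sequence, _interval_between

#: "20 weeks apart" boundary in days; the bounds are strict on both sides
#: (gap < 140 supports an age correction, gap > 140 an exclusion; exactly
#: 140 is neither, and resolves to deletion at Step 9.4).
TWENTY_WEEKS_DAYS = 140

#: administrative delay allowed between death and a recorded service date
DEATH_ALLOWANCE_DAYS = 3

BABY_YOB_VALID = (1920, 2014)
MOTHER_YOB_VALID = (1900, 2014)


@dataclass
class DobReconciliation:
    baby_ppn: str
    perinatal_dob: pd.Timestamp
    candidate_patient_dobs: list = field(default_factory=list)
    accepted_alternative: object = None
    n_age_corrected: int = 0
    n_deletion: int = 0


def _shares_component(d1, d2) -> bool:
    return ((d1.month == d2.month and d1.year == d2.year) or
            (d1.month == d2.month and d1.day == d2.day) or
            (d1.day == d2.day and d1.year == d2.year))


def _close_or_shared(d1, d2) -> bool:
    return _shares_component(d1, d2) or abs((d1 - d2).days) < TWENTY_WEEKS_DAYS


def _mother_consistent_with(view: pd.DataFrame, mum: str, baby: str,
                            new_dob) -> bool:
    """Would replacing *baby*'s DOB by *new_dob* keep the mother's pregnancy
    intervals non-negative and her parity sequence logical?"""
    firsts = view[(view["mum_ppn"].astype(str) == mum) &
                  (view["birth_order"] == 1)].copy()
    firsts.loc[firsts["baby_ppn"].astype(str) == baby, "baby_dob"] = new_dob
    firsts = firsts.sort_values(["baby_dob", "record_id"])
    rows = [r for _, r in firsts.iterrows()]
    for prior, nxt in zip(rows, rows[1:]):
        if prior["baby_dob"] == nxt["baby_dob"]:
            continue
        iv = _interval_between(prior, nxt)
        if iv is not None and iv < 0:
            return False
    if classify_parity_sequence(firsts["parity"]) == "illogical":
        return False
    return True


def reconcile_baby_dob(perinatal: pd.DataFrame, encounters: pd.DataFrame,
                       ledger: FlagLedger, review: ReviewQueue,
                       yob_valid: tuple[int, int] = BABY_YOB_VALID
                       ) -> list[DobReconciliation]:
    """Step 9 — reconcile the perinatal baby DOB against the patient DOB on
    the baby's hospital/ED records.

    When the perinatal DOB matches none of the patient DOBs, a patient DOB
    lying inside a maternal birth-delivery admission window (and passing the
    sibling and interval/parity safeguards) becomes the baby's updated DOB.
    Records whose patient DOB still disagrees with the updated DOB get an
    age correction when the two dates share month+year, month+day or
    day+year or lie under 20 weeks apart; otherwise the record is flagged
    for deletion.
    """
    results: list[DobReconciliation] = []
    view = active_perinatal(perinatal, ledger)
    if view.empty or encounters.empty:
        return results

    enc = active_records(encounters, ledger)
    enc_baby = enc[(enc["role"] == "baby") &
                   enc["source"].isin(["hospital", "ed"]) &
                   enc["patient_dob"].notna()].copy()
    yob = enc_baby["patient_dob"].dt.year
    enc_baby = enc_baby[(yob >= yob_valid[0]) & (yob <= yob_valid[1])]

    baby_first = (view.sort_values("record_id")
                      .groupby(view.sort_values("record_id")["baby_ppn"].astype(str))
                      .first())
    patient_dobs = {ppn: sorted(set(g["patient_dob"]))
                    for ppn, g in enc_baby.groupby(enc_baby["ppn"].astype(str))}

    delivery_windows: dict[str, list[tuple]] = {}
    deliv = enc[(enc["role"] == "mother") & (enc["source"] == "hospital") &
                (enc["is_delivery"] == 1)]
    for mum, g in deliv.groupby(deliv["ppn"].astype(str)):
        delivery_windows[mum] = list(zip(g["admission_date"], g["separation_date"]))

    def _in_delivery_window(mum: str, d) -> bool:
        return any(a <= d <= s for a, s in delivery_windows.get(mum, []))

    # 9.3 — alternative DOB search for mismatching babies
    for baby, dobs in sorted(patient_dobs.items()):
        if baby not in baby_first.index:
            continue
        row = baby_first.loc[baby]
        per_dob = row["baby_dob"]
        if per_dob in dobs:
            continue
        mum = str(row["mum_ppn"])
        rec = DobReconciliation(baby, per_dob, candidate_patient_dobs=dobs)
        results.append(rec)
        if _in_delivery_window(mum, per_dob):
            continue  # the perinatal date itself is plausible; leave as is
        candidates = []
        siblings = view[(view["mum_ppn"].astype(str) == mum) &
                        (view["baby_ppn"].astype(str) != baby)]
        for d in dobs:
            if not _in_delivery_window(mum, d):
                continue
            clash = siblings[(siblings["baby_dob"] == d) &
                             ~((siblings["plurality"] >= 2) &
                               (int(row["plurality"]) >= 2))]
            if not clash.empty:
                continue  # equals another (non-plural) child's DOB
            if not _mother_consistent_with(view, mum, baby, d):
                continue
            candidates.append(d)
        if len(candidates) == 1:
            alt = candidates[0]
            rec.accepted_alternative = alt
            targets = view[view["baby_ppn"].astype(str) == baby]
            for _, t in targets.iterrows():
                ledger.correct(str(t["record_id"]), "baby_dob",
                               t["baby_dob"], alt, "S9.3")
        elif len(candidates) > 1:
            review.add("S9.3", [baby],
                       f"{len(candidates)} patient DOBs each fall in a "
                       f"delivery admission window")

    # 9.4 — correct baby age or delete records disagreeing with updated DOB
    view = active_perinatal(perinatal, ledger)   # updated DOBs applied
    updated = {str(p): d for p, d in zip(view["baby_ppn"], view["baby_dob"])}
    by_baby = {r.baby_ppn: r for r in results}
    work = enc_baby.copy()
    work["upd_dob"] = work["ppn"].astype(str).map(updated)
    work = work[work["upd_dob"].notna() & (work["patient_dob"] != work["upd_dob"])]
    for row in work.sort_values("record_id").itertuples(index=False):
        ppn = str(row.ppn)
        upd = row.upd_dob
        rec = by_baby.get(ppn)
        if rec is None:
            rec = DobReconciliation(ppn, upd, candidate_patient_dobs=[])
            results.append(rec)
            by_baby[ppn] = rec
        if _close_or_shared(upd, row.patient_dob):
            age = max(0, (row.admission_date - upd).days // 365)
            ledger.correct(str(row.record_id), "patient_age",
                           row.patient_age, age, "S9.4")
            rec.n_age_corrected += 1
        else:
            ledger.flag("record", str(row.record_id), "deletion", "S9.4",
                        reason_code="dob_mismatch",
                        detail=f"patient DOB {row.patient_dob.date()} vs "
                               f"updated {upd.date()}")
            rec.n_deletion += 1
    return results


def check_congenital_consistency(perinatal: pd.DataFrame,
                                 congenital: pd.DataFrame,
                                 ledger: FlagLedger,
                                 review: ReviewQueue) -> int:
    """Step 10 — a congenital-condition notification disagreeing with the
    perinatal record on both DOB and birthweight.  When the congenital DOB
    equals a different child of the same mother, the children's records have
    been crossed by the linkage and the mother is excluded; otherwise the
    case goes to review.  Returns the number of cases found."""
    n_cases = 0
    if congenital is None or congenital.empty:
        return n_cases
    view = active_perinatal(perinatal, ledger)
    cong = active_records(congenital, ledger)
    per_baby = (view.sort_values("record_id")
                    .groupby(view.sort_values("record_id")["baby_ppn"].astype(str))
                    .first())
    for _, crow in cong.sort_values("record_id").iterrows():
        baby = str(crow["baby_ppn"])
        if baby not in per_baby.index:
            continue
        prow = per_baby.loc[baby]
        dob_differs = (pd.notna(crow["baby_dob"]) and
                       crow["baby_dob"] != prow["baby_dob"])
        bw_differs = (pd.notna(crow["birthweight"]) and
                      pd.notna(prow["birthweight"]) and
                      int(crow["birthweight"]) != int(prow["birthweight"]))
        if not (dob_differs and bw_differs):
            continue
        n_cases += 1
        mum = str(prow["mum_ppn"])
        siblings = view[(view["mum_ppn"].astype(str) == mum) &
                        (view["baby_ppn"].astype(str) != baby)]
        if (siblings["baby_dob"] == crow["baby_dob"]).any():
            ledger.flag("person", mum, "exclusion", "S10.3",
                        reason_code="congenital_sibling_dob",
                        detail=f"congenital DOB of {baby} equals a sibling's DOB")
        else:
            review.add("S10.3", [str(crow["record_id"]), baby],
                       "congenital DOB and birthweight both differ from perinatal")
    return n_cases


def _mother_yob_pool(view: pd.DataFrame, encounters: pd.DataFrame,
                     valid: tuple[int, int]) -> pd.DataFrame:
    """Per-record mother YOBs from perinatal and encounter data, invalid
    values removed."""
    per = pd.DataFrame({"mum_ppn": view["mum_ppn"].astype(str),
                        "yob": view["mother_yob"].astype("Int64")})
    enc = encounters[(encounters["role"] == "mother") &
                     encounters["patient_yob"].notna()]
    enc = pd.DataFrame({"mum_ppn": enc["ppn"].astype(str),
                        "yob": enc["patient_yob"].astype("Int64")})
    pool = pd.concat([per, enc], ignore_index=True).dropna()
    return pool[(pool["yob"] >= valid[0]) & (pool["yob"] <= valid[1])]


def check_mother_yob(perinatal: pd.DataFrame, encounters: pd.DataFrame,
                     ledger: FlagLedger,
                     valid: tuple[int, int] = MOTHER_YOB_VALID) -> list[str]:
    """Step 11 — mothers whose records carry two or more years of birth
    outside the range observed in perinatal data, or more than three
    different years of birth, are excluded."""
    flagged: list[str] = []
    view = active_perinatal(perinatal, ledger)
    if view.empty:
        return flagged
    per_yob = view["mother_yob"].dropna()
    lo, hi = int(per_yob.min()), int(per_yob.max())
    enc = active_records(encounters, ledger)
    pool = _mother_yob_pool(view, enc, valid)
    pool = pool[pool["mum_ppn"].isin(set(view["mum_ppn"].astype(str)))]
    for mum, g in pool.groupby("mum_ppn", sort=True):
        n_out = int(((g["yob"] < lo) | (g["yob"] > hi)).sum())
        n_distinct = g["yob"].nunique()
        if n_out >= 2 or n_distinct > 3:
            ledger.flag("person", mum, "exclusion", "S11.4",
                        reason_code="yob_inconsistent",
                        detail=f"{n_out} out-of-range [{lo},{hi}], "
                               f"{n_distinct} distinct YOBs")
            flagged.append(mum)
    return flagged


def check_mother_sex(perinatal: pd.DataFrame, encounters: pd.DataFrame,
                     ledger: FlagLedger,
                     valid: tuple[int, int] = MOTHER_YOB_VALID) -> list[str]:
    """Step 12 — two or more of a mother's records coded male together with
    more than one year and/or month of birth excludes the mother."""
    view = active_perinatal(perinatal, ledger)
    if view.empty:
        return []
    enc = active_records(encounters, ledger)
    menc = enc[(enc["role"] == "mother") &
               enc["ppn"].astype(str).isin(set(view["mum_ppn"].astype(str)))].copy()
    if not menc.empty:
        invalid = menc["patient_yob"].notna() & (
            (menc["patient_yob"] < valid[0]) | (menc["patient_yob"] > valid[1]))
        menc = menc[~invalid]
    pool = _mother_yob_pool(view, menc, valid)
    flagged = []
    for mum, g in menc.groupby(menc["ppn"].astype(str), sort=True):
        n_male = int((g["patient_sex"].astype(str) == "male").sum())
        if n_male < 2:
            continue
        yobs = pool.loc[pool["mum_ppn"] == mum, "yob"].nunique()
        mobs = g["month_of_birth"].dropna().nunique()
        if yobs > 1 or mobs > 1:
            ledger.flag("person", mum, "exclusion", "S12.2",
                        reason_code="sex_male_conflict",
                        detail=f"{n_male} male-coded records, {yobs} YOBs, "
                               f"{mobs} months of birth")
            flagged.append(mum)
    return flagged


def check_birth_after_hysterectomy(perinatal: pd.DataFrame,
                                   encounters: pd.DataFrame,
                                   hysterectomy_codes: list[str],
                                   ledger: FlagLedger) -> list[str]:
    """Step 13 — a delivery after hospital separation for a total
    hysterectomy is biologically impossible.  Skipped (returns empty) when
    no procedure code list is configured."""
    if not hysterectomy_codes:
        return []
    codes = set(hysterectomy_codes)
    view = active_perinatal(perinatal, ledger)
    if view.empty:
        return []
    enc = active_records(encounters, ledger)
    hosp = enc[(enc["role"] == "mother") & (enc["source"] == "hospital") &
               enc["procedure_codes"].notna()]
    flagged = []
    last_delivery = view.groupby(view["mum_ppn"].astype(str))["baby_dob"].max()
    for mum, g in hosp.groupby(hosp["ppn"].astype(str), sort=True):
        if mum not in last_delivery.index:
            continue
        has_hyst = g["procedure_codes"].astype(str).map(
            lambda s: bool(codes & set(s.split(";"))))
        seps = g.loc[has_hyst, "separation_date"]
        if seps.empty:
            continue
        if (seps < last_delivery.loc[mum]).any():
            ledger.flag("person", mum, "exclusion", "S13.3",
                        reason_code="birth_after_hysterectomy",
                        detail=f"hysterectomy separation "
                               f"{seps.min().date()} precedes delivery "
                               f"{last_delivery.loc[mum].date()}")
            flagged.append(mum)
    return flagged


def check_dob_after_discharge(perinatal: pd.DataFrame,
                              encounters: pd.DataFrame,
                              ledger: FlagLedger) -> dict:
    """Step 14 — the (Step-9 updated) baby DOB falling after the record's
    separation date.  A gap of more than 20 weeks between the updated DOB
    and the record's patient DOB excludes the baby (and, via family
    propagation, the mother); otherwise the record is deleted.  Must run
    after Step 9."""
    out = {"exclusions": [], "deletions": []}
    view = active_perinatal(perinatal, ledger)
    if view.empty or encounters.empty:
        return out
    updated = {str(p): d for p, d in zip(view["baby_ppn"], view["baby_dob"])}
    enc = active_records(encounters, ledger)
    enc_baby = enc[(enc["role"] == "baby") &
                   enc["source"].isin(["hospital", "ed"])].copy()
    enc_baby["upd_dob"] = enc_baby["ppn"].astype(str).map(updated)
    enc_baby = enc_baby[enc_baby["upd_dob"].notna() &
                        enc_baby["separation_date"].notna() &
                        (enc_baby["upd_dob"] > enc_baby["separation_date"])]
    for row in enc_baby.sort_values("record_id").itertuples(index=False):
        ppn = str(row.ppn)
        upd = row.upd_dob
        gap = None if pd.isna(row.patient_dob) else \
            abs((upd - row.patient_dob).days)
        if gap is not None and gap > TWENTY_WEEKS_DAYS:
            ledger.flag("person", ppn, "exclusion", "S14.3",
                        reason_code="dob_after_discharge",
                        detail=f"updated DOB {upd.date()} after separation, "
                               f"{gap} d from patient DOB")
            out["exclusions"].append(ppn)
        else:
            ledger.flag("record", str(row.record_id), "deletion", "S14.3",
                        reason_code="dob_after_discharge",
                        detail=f"updated DOB {upd.date()} after separation "
                               f"{row.separation_date.date()}")
            out["deletions"].append(str(row.record_id))
    return out


def check_service_after_death(perinatal: pd.DataFrame,
                              encounters: pd.DataFrame,
                              deaths: pd.DataFrame,
                              ledger: FlagLedger,
                              allowance_days: int = DEATH_ALLOWANCE_DAYS
                              ) -> list[str]:
    """Step 15 — health-service use more than the administrative allowance
    after the date of death excludes the person (children propagate to the
    mother)."""
    flagged: list[str] = []
    if deaths is None or deaths.empty:
        return flagged
    dview = active_records(deaths, ledger)
    death_date = dview.groupby(dview["ppn"].astype(str))["date_of_death"].min()
    enc = active_records(encounters, ledger) if not encounters.empty else encounters
    view = active_perinatal(perinatal, ledger)
    for ppn, dod in death_date.sort_index().items():
        limit = dod + timedelta(days=allowance_days)
        late = False
        if not enc.empty:
            mine = enc[enc["ppn"].astype(str) == ppn]
            if (mine["separation_date"] > limit).any():
                late = True
        if not late and not view.empty:
            deliveries = view.loc[view["mum_ppn"].astype(str) == ppn, "baby_dob"]
            if (deliveries > limit).any():
                late = True
        if late:
            ledger.flag("person", ppn, "exclusion", "S15.4",
                        reason_code="service_after_death",
                        detail=f"service use after {dod.date()} + "
                               f"{allowance_days} d")
            flagged.append(ppn)
    return flagged


def check_admission_after_discharge(encounters: pd.DataFrame,
                                    ledger: FlagLedger) -> list[str]:
    """Step 16 — admission (or ED arrival) after the separation date marks
    the record for deletion; same-day episodes are legitimate."""
    flagged: list[str] = []
    if encounters.empty:
        return flagged
    enc = active_records(encounters, ledger)
    bad = enc[enc["admission_date"] > enc["separation_date"]]
    for rid in sorted(bad["record_id"].astype(str)):
        ledger.flag("record", rid, "deletion", "S16.1",
                    reason_code="admission_after_discharge")
        flagged.append(rid)
    return flagged
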