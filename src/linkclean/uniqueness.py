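"""Uniqueness of records: within-source duplicates, death-registration
completeness, and uniqueness of the baby person number across mothers.

A person identifier shared by perinatal records of different mothers is
biologically impossible and marks a linkage error: all involved mothers are
flagged for exclusion.  Multiple records of the same birth under one mother
are adjudicated on auxiliary fields (:data:`linkclean.model.REVIEW_FIELDS`)
and flagged as duplicates when the entries agree; disagreement excludes the
mother, and thin evidence goes to the review queue rather than being
decided silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import REVIEW_FIELDS, FlagLedger, ReviewQueue, active_records


@dataclass
class DupGroup:
    record_ids: list[str]
    kind: str                      # identical | partial
    keep_id: str | None
    flagged_ids: list[str]
    fields_compared: list[str] = field(default_factory=list)


@dataclass
class DuplicateReport:
    table: str
    groups: list[DupGroup] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return sum(len(g.flagged_ids) for g in self.groups)


def find_identical_duplicates(df: pd.DataFrame, table: str,
                              ledger: FlagLedger,
                              id_col: str = "record_id") -> DuplicateReport:
    """Step 1.1 — rows equal on every field except the unique record id.

    Within each group the first record by ascending id is kept; the rest are
    flagged ``duplicate``.
    """
    report = DuplicateReport(table=table)
    if df.empty:
        return report
    value_cols = [c for c in df.columns if c != id_col]
    work = df.copy()
    work["_key"] = work[value_cols].astype(str).agg("\x1f".join, axis=1)
    for _, grp in work.groupby("_key", sort=True):
        if len(grp) < 2:
            continue
        ids = sorted(grp[id_col].astype(str))
        keep, rest = ids[0], ids[1:]
        for rid in rest:
            ledger.flag("record", rid, "duplicate", "S1.1",
                        reason_code="identical_duplicate",
                        detail=f"identical to {keep} in {table}")
        report.groups.append(DupGroup(ids, "identical", keep, rest, value_cols))
    return report


def find_partial_death_duplicates(deaths: pd.DataFrame,
                                  encounters: pd.DataFrame,
                                  ledger: FlagLedger,
                                  review: ReviewQueue) -> DuplicateReport:
    """Step 1.2 — several death records for one person within one stream.

    Identical duplicates must already be flagged.  Equal dates of death keep
    one record; differing dates are adjudicated against hospital/ED evidence
    (a separation with deceased discharge status supports that date);
    unresolvable cases go to the review queue.
    """
    report = DuplicateReport(table="deaths")
    if deaths.empty:
        return report
    view = active_records(deaths, ledger)

    deceased_sep: dict[str, set] = {}
    if not encounters.empty:
        ev = encounters[encounters["discharge_status"].astype(str) == "deceased"]
        for ppn, grp in ev.groupby(ev["ppn"].astype(str)):
            deceased_sep[ppn] = set(grp["separation_date"].dropna())

    for (ppn, _stream), grp in view.groupby(
            [view["ppn"].astype(str), view["stream"].astype(str)], sort=True):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("record_id")
        ids = grp["record_id"].astype(str).tolist()
        dates = grp["date_of_death"].tolist()
        if len(set(dates)) == 1:
            keep, rest = ids[0], ids[1:]
            for rid in rest:
                ledger.flag("record", rid, "duplicate", "S1.2",
                            reason_code="partial_death_duplicate",
                            detail=f"same date of death as {keep} for {ppn}")
            report.groups.append(DupGroup(ids, "partial", keep, rest,
                                          ["date_of_death"]))
            continue
        evidence = deceased_sep.get(ppn, set())
        supported = sorted({d for d in dates if d in evidence})
        if len(supported) == 1:
            keep_date = supported[0]
            keep = next(r for r, d in zip(ids, dates) if d == keep_date)
            rest = [r for r, d in zip(ids, dates) if d != keep_date]
            for rid in rest:
                ledger.flag("record", rid, "duplicate", "S1.2",
                            reason_code="partial_death_duplicate",
                            detail=f"deceased discharge supports {keep_date.date()}")
            report.groups.append(DupGroup(ids, "partial", keep, rest,
                                          ["date_of_death", "discharge_status"]))
        else:
            review.add("S1.2", ids,
                       f"{ppn}: differing dates of death, no decisive "
                       f"discharge evidence")
    return report


def check_death_registration_completeness(
        deaths: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Step 2.1 — persons in the causes-of-death stream but absent from the
    death registration stream.

    Only applies where a jurisdiction delivers the two streams separately;
    jurisdictions without a causes-of-death stream are skipped.  Returns
    ``(offending_ppns, skipped_jurisdictions)``; clean data yields no cases
    because cause-of-death coding follows registration deterministically.
    """
    offenders: list[str] = []
    skipped: list[str] = []
    if deaths.empty:
        return offenders, skipped
    for jur, grp in deaths.groupby(deaths["jurisdiction"].astype(str), sort=True):
        streams = set(grp["stream"].astype(str))
        if "causes_of_death" not in streams:
            skipped.append(jur)
            continue
        cod = set(grp.loc[grp["stream"] == "causes_of_death", "ppn"].astype(str))
        reg = set(grp.loc[grp["stream"] == "registration", "ppn"].astype(str))
        offenders.extend(sorted(cod - reg))
    return offenders, skipped


def _adjudicate_same_mother(grp: pd.DataFrame) -> tuple[str, list[str]]:
    """Compare auxiliary fields across records of one baby under one mother.

    Returns ``("agree", keep+flag ids)``, ``("disagree", ids)`` or
    ``("thin", ids)`` when fewer than 3 fields are comparable.
    """
    comparable = []
    for f in REVIEW_FIELDS:
        vals = grp[f]
        if vals.isna().any():
            continue
        comparable.append(f)
    ids = sorted(grp["record_id"].astype(str))
    if len(comparable) < 3:
        return "thin", ids
    for f in comparable:
        if grp[f].nunique(dropna=False) > 1:
            return "disagree", ids
    return "agree", ids


def check_baby_ppn_uniqueness(perinatal: pd.DataFrame, ledger: FlagLedger,
                              review: ReviewQueue) -> DuplicateReport:
    """Step 3 — one baby PPN on records of different mothers, or repeated
    under one mother.

    Different mothers sharing a baby PPN: all flagged ``exclusion`` (S3.3).
    Same mother: records agreeing on the auxiliary fields are duplicates
    (one kept, S3.4); disagreement excludes the mother; fewer than three
    comparable fields goes to review.
    """
    report = DuplicateReport(table="perinatal")
    view = active_records(perinatal, ledger)
    if view.empty:
        return report
    for baby, grp in view.groupby(view["baby_ppn"].astype(str), sort=True):
        if len(grp) < 2:
            continue
        mothers = sorted(set(grp["mum_ppn"].astype(str)))
        if len(mothers) > 1:
            for mum in mothers:
                ledger.flag("person", mum, "exclusion", "S3.3",
                            reason_code="shared_baby_ppn",
                            detail=f"baby {baby} mapped to mothers {mothers}")
            continue
        verdict, ids = _adjudicate_same_mother(grp)
        if verdict == "agree":
            keep, rest = ids[0], ids[1:]
            for rid in rest:
                ledger.flag("record", rid, "duplicate", "S3.4",
                            reason_code="baby_double_entry",
                            detail=f"repeat of baby {baby}, agrees with {keep}")
            report.groups.append(DupGroup(ids, "partial", keep, rest,
                                          REVIEW_FIELDS))
        elif verdict == "disagree":
            ledger.flag("person", mothers[0], "exclusion", "S3.4",
                        reason_code="baby_ppn_conflict",
                        detail=f"conflicting repeat records for baby {baby}")
        else:
            review.add("S3.4", ids,
                       f"baby {baby}: <3 comparable fields for adjudication")
    return report
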