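"""Core domain model for linked perinatal data cleaning.

Tables are plain :class:`pandas.DataFrame` objects with fixed schemas
(see the ``*_COLUMNS`` constants).  All cleaning decisions are recorded in
an append-only :class:`FlagLedger`; source tables are never mutated in
place — every step derives filtered "views" from the original frames plus
the ledger.

Date arithmetic is day-granular.  The conception date of a delivery is

    conception = baby_dob - 7 * gestational_age + 14 days

(gestational age in completed weeks), and the interval between two
consecutive pregnancies of one woman is

    interval = conception(next) - delivery(prior) - 7 days

which is negative only when the next child was conceived before the prior
child was delivered — a biologically impossible ordering that indicates a
false positive link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable

import pandas as pd

__all__ = [
    "PERINATAL_COLUMNS",
    "ENCOUNTER_COLUMNS",
    "DEATH_COLUMNS",
    "CONGENITAL_COLUMNS",
    "CLAIM_COLUMNS",
    "MAPPING_COLUMNS",
    "REVIEW_FIELDS",
    "NotComputable",
    "conception_date",
    "pregnancy_interval",
    "FlagEntry",
    "Correction",
    "FlagLedger",
    "ReviewQueue",
    "IdentityResolution",
    "apply_corrections",
    "active_records",
    "active_perinatal",
    "propagate_exclusions",
]

# ---------------------------------------------------------------------------
# Table schemas (CSV column order)

PERINATAL_COLUMNS = [
    "record_id", "jurisdiction", "mum_ppn", "baby_ppn", "baby_dob",
    "gestational_age", "birthweight", "parity", "plurality", "birth_order",
    "mother_yob", "mother_age", "apgar5", "discharge_status", "postcode",
    "country_of_birth", "hospital",
]

ENCOUNTER_COLUMNS = [
    "record_id", "jurisdiction", "ppn", "role", "source",
    "admission_date", "separation_date", "patient_dob", "patient_yob",
    "patient_age", "patient_sex", "month_of_birth", "procedure_codes",
    "discharge_status", "is_delivery",
]

DEATH_COLUMNS = ["record_id", "jurisdiction", "ppn", "date_of_death", "stream"]

CONGENITAL_COLUMNS = ["record_id", "baby_ppn", "baby_dob", "birthweight"]

CLAIM_COLUMNS = [
    "claim_id", "patid", "date_of_supply", "item_code",
    "month_of_birth", "year_of_birth",
]

MAPPING_COLUMNS = ["patid", "mum_ppn", "jurisdiction", "weight"]

#: Auxiliary perinatal fields used when adjudicating suspected multiple
#: entries of the same birth (baby DOB, plurality, birth order, birthweight,
#: gestational age, Apgar score, discharge status, mother's age, postcode,
#: country of birth, hospital).
REVIEW_FIELDS = [
    "baby_dob", "plurality", "birth_order", "birthweight", "gestational_age",
    "apgar5", "discharge_status", "mother_age", "postcode",
    "country_of_birth", "hospital",
]


class NotComputable(ValueError):
    """A derived quantity cannot be computed from the available fields."""


def _is_missing(value) -> bool:
    return value is None or value is pd.NaT or (
        isinstance(value, float) and pd.isna(value)
    ) or (value is pd.NA)


def conception_date(baby_dob, gestational_age):
    """Date of conception from delivery date and completed weeks of gestation.

    ``baby_dob - gestational_age * 7 days + 14 days``.  Accepts
    :class:`datetime.date` or :class:`pandas.Timestamp`; returns the same
    type.  Raises :class:`NotComputable` when gestation is missing.
    """
    if _is_missing(gestational_age):
        raise NotComputable("gestational age is missing")
    weeks = int(gestational_age)
    if weeks < 0:
        raise NotComputable(f"negative gestational age: {weeks}")
    return baby_dob - timedelta(days=7 * weeks - 14)


def pregnancy_interval(prior_delivery, next_baby_dob, next_gestation) -> int:
    """Days between a delivery and the conception of the next pregnancy.

    ``conception(next) - prior_delivery - 7 days`` where the 7-day margin
    allows for gestation being recorded in completed weeks.  May be
    negative; a negative interval flags the woman's records as a likely
    false positive link.
    """
    conc = conception_date(next_baby_dob, next_gestation)
    delta = conc - prior_delivery
    days = delta.days if isinstance(delta, timedelta) else int(delta / timedelta(days=1))
    return days - 7


# ---------------------------------------------------------------------------
# Flag ledger

#: flag kind -> scopes at which it is valid
_FLAG_SCOPES = {
    "exclusion": {"person"},
    "duplicate": {"record"},
    "deletion": {"record"},
    "review": {"person", "record"},
    "disregard_link": {"record"},
}


@dataclass(frozen=True)
class FlagEntry:
    scope: str
    target_id: str
    flag: str
    step_id: str
    reason_code: str = ""
    detail: str = ""


@dataclass(frozen=True)
class Correction:
    record_id: str
    field: str
    old_value: object
    new_value: object
    step_id: str


class FlagLedger:
    """Append-only register of cleaning decisions.

    Person-level ``exclusion`` flags mark likely false positive links;
    record-level ``duplicate``/``deletion`` flags mark rows to drop from
    derived views; field corrections record replacement values.  Nothing is
    ever removed or edited, and applying the ledger never mutates a source
    table — consumers call :func:`active_records` / :func:`apply_corrections`
    to derive views.
    """

    def __init__(self) -> None:
        self.entries: list[FlagEntry] = []
        self.corrections: list[Correction] = []
        self._seen: set[tuple] = set()
        self._seen_corr: set[tuple] = set()

    # -- flags --------------------------------------------------------------
    def flag(self, scope: str, target_id: str, flag: str, step_id: str,
             reason_code: str = "", detail: str = "") -> bool:
        """Append a flag entry. Returns False when an identical entry exists."""
        if flag not in _FLAG_SCOPES:
            raise ValueError(f"unknown flag kind: {flag!r}")
        if scope not in _FLAG_SCOPES[flag]:
            raise ValueError(
                f"flag {flag!r} not valid at scope {scope!r} (target {target_id})"
            )
        key = (scope, str(target_id), flag, step_id, reason_code)
        if key in self._seen:
            return False
        self._seen.add(key)
        self.entries.append(FlagEntry(scope, str(target_id), flag, step_id,
                                      reason_code, detail))
        return True

    def correct(self, record_id: str, fieldname: str, old_value, new_value,
                step_id: str) -> bool:
        key = (str(record_id), fieldname, step_id, repr(new_value))
        if key in self._seen_corr:
            return False
        self._seen_corr.add(key)
        self.corrections.append(
            Correction(str(record_id), fieldname, old_value, new_value, step_id))
        return True

    # -- queries ------------------------------------------------------------
    def excluded_persons(self) -> set[str]:
        return {e.target_id for e in self.entries
                if e.flag == "exclusion" and e.scope == "person"}

    def flagged_records(self, kinds: Iterable[str] = ("duplicate", "deletion")) -> set[str]:
        kinds = set(kinds)
        return {e.target_id for e in self.entries
                if e.scope == "record" and e.flag in kinds}

    def disregarded_links(self) -> set[str]:
        return {e.target_id for e in self.entries if e.flag == "disregard_link"}

    def exclusion_step(self, person_id: str) -> str | None:
        for e in self.entries:
            if e.flag == "exclusion" and e.target_id == person_id:
                return e.step_id
        return None

    def flags_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.scope, e.target_id, e.flag, e.step_id, e.reason_code, e.detail)
             for e in self.entries],
            columns=["scope", "target_id", "flag", "step_id", "reason_code", "detail"],
        )

    def corrections_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.record_id, c.field, str(c.old_value), str(c.new_value), c.step_id)
             for c in self.corrections],
            columns=["record_id", "field", "old_value", "new_value", "step_id"],
        )

    def counts_by_step(self) -> pd.DataFrame:
        df = self.flags_frame()
        if df.empty:
            return pd.DataFrame(columns=["step_id", "flag", "n"])
        return (df.groupby(["step_id", "flag"]).size()
                  .rename("n").reset_index())


class ReviewQueue:
    """Export queue for cases an automated rule declines to decide."""

    def __init__(self) -> None:
        self.items: list[dict] = []

    def add(self, step_id: str, target_ids: Iterable[str], evidence: str) -> None:
        self.items.append({
            "queue_id": f"Q{len(self.items) + 1:05d}",
            "step_id": step_id,
            "target_ids": ";".join(str(t) for t in target_ids),
            "evidence": evidence,
        })

    def targets_for_step(self, step_prefix: str) -> set[str]:
        out: set[str] = set()
        for item in self.items:
            if item["step_id"].startswith(step_prefix):
                out.update(item["target_ids"].split(";"))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.items, columns=["queue_id", "step_id", "target_ids", "evidence"])


@dataclass
class IdentityResolution:
    """Final mother-identifier assignment.

    ``final_ppn`` collapses, in order of precedence: accepted cross-state ID,
    accepted within-state cluster ID, the woman's own PPN.
    """

    cluster_assignments: dict[str, str] = field(default_factory=dict)
    cross_assignments: dict[str, str] = field(default_factory=dict)
    final_ppn: dict[str, str] = field(default_factory=dict)

    def resolve(self, mum_ppns: Iterable[str]) -> None:
        for ppn in sorted(set(str(p) for p in mum_ppns)):
            self.final_ppn[ppn] = self.cross_assignments.get(
                ppn, self.cluster_assignments.get(ppn, ppn))

    def to_frame(self) -> pd.DataFrame:
        rows = [(p, self.cluster_assignments.get(p, ""),
                 self.cross_assignments.get(p, ""), f)
                for p, f in sorted(self.final_ppn.items())]
        return pd.DataFrame(
            rows, columns=["mum_ppn", "cluster_id", "cross_id", "final_ppn_mum"])


# ---------------------------------------------------------------------------
# Derived views

def apply_corrections(df: pd.DataFrame, ledger: FlagLedger,
                      id_col: str = "record_id") -> pd.DataFrame:
    """Return a copy of *df* with ledger corrections overlaid (last wins)."""
    out = df.copy()
    if not ledger.corrections or out.empty:
        return out
    idx = pd.Index(out[id_col].astype(str))
    for corr in ledger.corrections:
        if corr.field not in out.columns:
            continue
        pos = idx.get_indexer([corr.record_id])
        if pos[0] >= 0:
            col = out.columns.get_loc(corr.field)
            out.iloc[pos[0], col] = corr.new_value
    return out


def active_records(df: pd.DataFrame, ledger: FlagLedger,
                   id_col: str = "record_id",
                   corrections: bool = True) -> pd.DataFrame:
    """View of *df* without duplicate/deletion-flagged rows, corrections applied."""
    out = apply_corrections(df, ledger, id_col) if corrections else df.copy()
    dropped = ledger.flagged_records()
    if dropped and not out.empty:
        out = out[~out[id_col].astype(str).isin(dropped)]
    return out


def active_perinatal(perinatal: pd.DataFrame, ledger: FlagLedger,
                     drop_excluded: bool = True) -> pd.DataFrame:
    """Perinatal view: corrections applied, flagged rows and (optionally)
    records of excluded families removed."""
    out = active_records(perinatal, ledger)
    if drop_excluded and not out.empty:
        excluded = ledger.excluded_persons()
        if excluded:
            mask = out["mum_ppn"].astype(str).isin(excluded) | \
                out["baby_ppn"].astype(str).isin(excluded)
            out = out[~mask]
    return out


def propagate_exclusions(perinatal: pd.DataFrame, ledger: FlagLedger) -> int:
    """Close person-level exclusions over the mother-child family graph.

    An excluded child always excludes the mother, and an excluded mother
    marks all of her children as members of an excluded family.  Run after
    every person-level step; propagated entries inherit the step id of the
    triggering exclusion with reason code ``family``.  Returns the number of
    newly flagged persons.
    """
    mum_of: dict[str, set[str]] = {}
    babies_of: dict[str, set[str]] = {}
    for mum, baby in zip(perinatal["mum_ppn"].astype(str),
                         perinatal["baby_ppn"].astype(str)):
        mum_of.setdefault(baby, set()).add(mum)
        babies_of.setdefault(mum, set()).add(baby)

    added = 0
    frontier = sorted(ledger.excluded_persons())
    seen = set(frontier)
    while frontier:
        person = frontier.pop()
        step = ledger.exclusion_step(person) or "S0"
        relatives = sorted(mum_of.get(person, set()) | babies_of.get(person, set()))
        for rel in relatives:
            if rel in seen:
                continue
            ledger.flag("person", rel, "exclusion", step, reason_code="family",
                        detail=f"family of excluded person {person}")
            seen.add(rel)
            frontier.append(rel)
            added += 1
    return added
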