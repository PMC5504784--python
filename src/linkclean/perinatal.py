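"""Within-person perinatal consistency: plausibility of birthweight and
gestation, birth order versus plurality, pregnancy intervals, parity
imputation and parity-sequence checks.

Parity (number of previous pregnancies of at least 20 weeks) must increase
strictly across a woman's deliveries, so a woman's record set can be checked
against itself: the expected number of pregnancies implied by the span of
parity values (``highest - lowest + 1``) is compared with the number of
delivery records actually present.  A moderate shortfall of records suggests
intervening births in another jurisdiction; a surplus of records relative to
an illogical parity sequence suggests records of two different women fused by
a false positive link and excludes the woman.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (REVIEW_FIELDS, FlagLedger, ReviewQueue, active_perinatal,
                    pregnancy_interval)

#: strict upper bound, in days, for the "interval < 40 weeks" conditions
FORTY_WEEKS_DAYS = 280


# ---------------------------------------------------------------------------
# Step 4 — birthweight x gestational age tabulation (no changes ever made:
# outlying values can have medical causes)

BW_LABELS = ["missing", "<400", "400-999", "1000-1999", "2000-4999", ">=5000"]
GEST_LABELS = ["missing", "<20", "20-26", "27-36", "37-44", ">=45"]


@dataclass
class BirthweightGestationTabulation:
    table: pd.DataFrame                     # 6x6 counts, rows birthweight
    n_gest_lt20_bw_lt400: int
    n_gest_ge45: int
    n_bw_lt1000_gest_ge45: int
    n_bw_ge2000_gest_le26: int


def _bw_category(bw) -> str:
    if pd.isna(bw):
        return "missing"
    bw = int(bw)
    if bw < 400:
        return "<400"
    if bw < 1000:
        return "400-999"
    if bw < 2000:
        return "1000-1999"
    if bw < 5000:
        return "2000-4999"
    return ">=5000"


def _gest_category(g) -> str:
    if pd.isna(g):
        return "missing"
    g = int(g)
    if g < 20:
        return "<20"
    if g <= 26:
        return "20-26"
    if g <= 36:
        return "27-36"
    if g <= 44:
        return "37-44"
    return ">=45"


def tabulate_birthweight_gestation(
        perinatal: pd.DataFrame) -> BirthweightGestationTabulation:
    """Step 4 — cross-tabulate birthweight with gestational age and count
    outlying combinations.  Reporting only; no flags or corrections."""
    bw_cat = pd.Categorical(perinatal["birthweight"].map(_bw_category),
                            categories=BW_LABELS)
    g_cat = pd.Categorical(perinatal["gestational_age"].map(_gest_category),
                           categories=GEST_LABELS)
    table = pd.crosstab(bw_cat, g_cat, dropna=False)
    table = table.reindex(index=BW_LABELS, columns=GEST_LABELS, fill_value=0)

    bw = perinatal["birthweight"]
    g = perinatal["gestational_age"]
    return BirthweightGestationTabulation(
        table=table,
        n_gest_lt20_bw_lt400=int(((g < 20) & (bw < 400)).sum()),
        n_gest_ge45=int((g >= 45).sum()),
        n_bw_lt1000_gest_ge45=int(((bw < 1000) & (g >= 45)).sum()),
        n_bw_ge2000_gest_le26=int(((bw >= 2000) & (g <= 26)).sum()),
    )


# ---------------------------------------------------------------------------
# Delivery grouping for plural births

def _group_deliveries(records: pd.DataFrame) -> list[pd.DataFrame]:
    """Cluster one mother's plural-birth records into deliveries.

    Records belong to the same delivery when their DOBs differ by no more
    than the difference in gestational age x 7 days (twins can be born days
    apart in complicated deliveries).  Undersized adjacent clusters of the
    same plurality within 35 days are merged as suspected DOB typos.
    """
    recs = records.sort_values(["baby_dob", "birth_order", "record_id"])
    groups: list[list[int]] = []
    for idx in recs.index:
        placed = False
        if groups:
            g0 = groups[-1][0]
            gap = abs((recs.loc[idx, "baby_dob"] - recs.loc[g0, "baby_dob"]).days)
            ga, gb = recs.loc[g0, "gestational_age"], recs.loc[idx, "gestational_age"]
            allowed = 0 if (pd.isna(ga) or pd.isna(gb)) else abs(int(ga) - int(gb)) * 7
            if gap <= allowed and len(groups[-1]) < int(recs.loc[g0, "plurality"]):
                groups[-1].append(idx)
                placed = True
        if not placed:
            groups.append([idx])
    # merge adjacent undersized clusters (same plurality, <=35 days apart)
    merged: list[list[int]] = []
    for g in groups:
        if merged:
            prev = merged[-1]
            p_prev = int(recs.loc[prev[0], "plurality"])
            p_cur = int(recs.loc[g[0], "plurality"])
            gap = abs((recs.loc[g[0], "baby_dob"] -
                       recs.loc[prev[0], "baby_dob"]).days)
            if (p_prev == p_cur and len(prev) < p_prev and
                    len(prev) + len(g) <= p_prev and gap <= 35):
                prev.extend(g)
                continue
        merged.append(list(g))
    return [recs.loc[g] for g in merged]


def validate_birth_order(perinatal: pd.DataFrame, ledger: FlagLedger,
                         review: ReviewQueue) -> dict:
    """Step 5 — birth order versus pregnancy plurality.

    Implausible orders (birth order exceeding plurality) are reported for
    review.  Within each plural delivery the expected sequence of birth
    1..k is derived; consistent typo patterns are corrected, supernumerary
    records identical on the adjudication fields are flagged as duplicates,
    and a lone divergent DOB among same-gestation siblings is corrected.
    """
    view = active_perinatal(perinatal, ledger)
    summary = {"implausible": 0, "order_corrected": 0, "dob_corrected": 0,
               "duplicates": 0}
    if view.empty:
        return summary

    implausible = view[view["birth_order"] > view["plurality"]]
    for rid in sorted(implausible["record_id"].astype(str)):
        review.add("S5.1", [rid], "birth order exceeds plurality")
        summary["implausible"] += 1

    plural = view[view["plurality"] >= 2]
    for _mum, recs in plural.groupby(plural["mum_ppn"].astype(str), sort=True):
        for grp in _group_deliveries(recs):
            k = int(grp["plurality"].iloc[0])
            if len(grp) > k:
                # supernumerary entry: duplicate if it mirrors a sibling
                grp = grp.sort_values("record_id")
                seen: dict[tuple, str] = {}
                for _, row in grp.iterrows():
                    key = tuple(str(row[f]) for f in REVIEW_FIELDS)
                    rid = str(row["record_id"])
                    if key in seen:
                        ledger.flag("record", rid, "duplicate", "S5.3",
                                    reason_code="supernumerary_plural",
                                    detail=f"mirrors {seen[key]}")
                        summary["duplicates"] += 1
                    else:
                        seen[key] = rid
                grp = grp[~grp["record_id"].astype(str).isin(
                    ledger.flagged_records(["duplicate"]))]
                if len(grp) != k:
                    review.add("S5.3", sorted(grp["record_id"].astype(str)),
                               "plural delivery with unexplained extra records")
                    continue
            if len(grp) < k:
                continue  # sibling record absent; order cannot be validated
            # DOB typo: equal gestations must share the delivery date
            gests = grp["gestational_age"]
            dobs = grp["baby_dob"]
            if gests.notna().all() and gests.nunique() == 1 and dobs.nunique() > 1:
                modal = dobs.mode().iloc[0]
                for _, row in grp.iterrows():
                    if row["baby_dob"] != modal:
                        ledger.correct(str(row["record_id"]), "baby_dob",
                                       row["baby_dob"], modal, "S5.3")
                        summary["dob_corrected"] += 1
                grp = grp.assign(baby_dob=modal)
            ordered = grp.sort_values(["baby_dob", "birth_order", "record_id"])
            for expected, (_, row) in enumerate(ordered.iterrows(), start=1):
                if int(row["birth_order"]) != expected:
                    ledger.correct(str(row["record_id"]), "birth_order",
                                   int(row["birth_order"]), expected, "S5.3")
                    summary["order_corrected"] += 1
    return summary


# ---------------------------------------------------------------------------
# Step 6 — interval between consecutive pregnancies

def _interval_between(prior_row, next_row) -> int | None:
    if pd.isna(next_row["gestational_age"]):
        return None
    return pregnancy_interval(prior_row["baby_dob"], next_row["baby_dob"],
                              int(next_row["gestational_age"]))


def _mother_first_rows(view: pd.DataFrame) -> dict[str, list[dict]]:
    """One row per delivery (birth order 1) per mother, sorted by baby DOB,
    as plain dicts for fast sequential rule evaluation."""
    firsts = view[view["birth_order"] == 1]
    f = firsts.sort_values(["mum_ppn", "baby_dob", "record_id"])
    out: dict[str, list[dict]] = {}
    for mum, rid, dob, gest, parity in zip(
            f["mum_ppn"].astype(str), f["record_id"].astype(str),
            f["baby_dob"], f["gestational_age"], f["parity"]):
        out.setdefault(mum, []).append(
            {"record_id": rid, "baby_dob": dob, "gestational_age": gest,
             "parity": parity})
    return out


def check_pregnancy_intervals(perinatal: pd.DataFrame,
                              ledger: FlagLedger) -> list[str]:
    """Step 6 — a conception preceding the prior delivery (negative
    interval) is biologically impossible: the mother is flagged for
    exclusion.  One record per delivery (birth order 1) is used; pairs with
    missing gestation are not assessable."""
    view = active_perinatal(perinatal, ledger)
    flagged: list[str] = []
    if view.empty:
        return flagged
    firsts = view[view["birth_order"] == 1]
    f = firsts.sort_values(["mum_ppn", "baby_dob", "record_id"]).copy()
    gest_days = (f["gestational_age"].astype("Float64") * 7 - 14).astype(float)
    conception = f["baby_dob"] - pd.to_timedelta(gest_days, unit="D")
    prior_dob = f.groupby(f["mum_ppn"].astype(str))["baby_dob"].shift(1)
    interval = (conception - prior_dob).dt.days - 7
    bad = f[interval < 0].assign(_interval=interval[interval < 0])
    for mum, grp in bad.groupby(bad["mum_ppn"].astype(str), sort=True):
        row = grp.iloc[0]
        if ledger.flag("person", mum, "exclusion", "S6.4",
                       reason_code="negative_interval",
                       detail=f"interval {int(row['_interval'])} d before "
                              f"{row['baby_dob'].date()}"):
            flagged.append(mum)
    return flagged


# ---------------------------------------------------------------------------
# Step 7 — imputation of missing parity

def classify_parity_sequence(values) -> str:
    """Classify an ordered parity sequence as ``logical`` (strictly
    increasing between every pair of consecutive records) or ``illogical``.
    Fewer than two values -> ``not_assessable``."""
    vals = [int(v) for v in values if not pd.isna(v)]
    if len(vals) < 2:
        return "not_assessable"
    return "logical" if all(a < b for a, b in zip(vals, vals[1:])) else "illogical"


def impute_missing_parity(perinatal: pd.DataFrame, ledger: FlagLedger) -> int:
    """Step 7 — fill missing parity where the neighbouring records pin the
    value down.

    Plural-birth records first borrow parity from their same-delivery
    siblings.  Then, per mother (one record per delivery), a single missing
    value is imputed from the adjacent parities subject to the 40-week
    inter-pregnancy interval conditions; mothers with one pregnancy, two or
    more missing values, parity zero in the second record (an error marker,
    since parity counts previous pregnancies), or an illogical sequence are
    left unchanged.  Returns the number of records corrected.
    """
    n_corrected = 0
    view = active_perinatal(perinatal, ledger)
    if view.empty:
        return 0
    missing_mums = set(
        view.loc[view["parity"].isna(), "mum_ppn"].astype(str))

    # 7.2 within-delivery fill for plural births
    plural = view[(view["plurality"] >= 2) &
                  view["mum_ppn"].astype(str).isin(missing_mums)]
    for _mum, recs in plural.groupby(plural["mum_ppn"].astype(str), sort=True):
        for grp in _group_deliveries(recs):
            vals = grp["parity"].dropna().unique()
            if len(vals) != 1 or not grp["parity"].isna().any():
                continue
            fill = int(vals[0])
            for _, row in grp[grp["parity"].isna()].iterrows():
                ledger.correct(str(row["record_id"]), "parity",
                               None, fill, "S7.2")
                n_corrected += 1

    # 7.3-7.5 per-mother imputation on one record per delivery
    view = active_perinatal(perinatal, ledger)   # re-derive with 7.2 applied
    firsts = view[(view["birth_order"] == 1) &
                  view["mum_ppn"].astype(str).isin(missing_mums)]
    for mum, recs in firsts.groupby(firsts["mum_ppn"].astype(str), sort=True):
        recs = recs.sort_values(["baby_dob", "record_id"])
        parities = recs["parity"].tolist()
        n = len(parities)
        n_missing = sum(pd.isna(p) for p in parities)
        if n < 2 or n_missing != 1:
            continue
        if not pd.isna(parities[1]) and int(parities[1]) == 0:
            continue  # parity 0 in the second record marks an error
        if classify_parity_sequence(parities) == "illogical":
            continue  # handled at Step 8
        pos = next(i for i, p in enumerate(parities) if pd.isna(p))
        rows = [r for _, r in recs.iterrows()]
        new_value = None
        step = None
        if pos == 0:
            nxt = int(parities[1])
            iv = _interval_between(rows[0], rows[1])
            if nxt == 1 or (nxt > 1 and iv is not None and iv < FORTY_WEEKS_DAYS):
                new_value, step = nxt - 1, "S7.5.1"
        elif pos == n - 1:
            iv = _interval_between(rows[pos - 1], rows[pos])
            if iv is not None and iv < FORTY_WEEKS_DAYS:
                new_value, step = int(parities[pos - 1]) + 1, "S7.5.2"
        else:
            prior, nxt = int(parities[pos - 1]), int(parities[pos + 1])
            diff = nxt - prior
            iv = _interval_between(rows[pos - 1], rows[pos])
            if diff == 2 or (diff > 2 and iv is not None and iv < FORTY_WEEKS_DAYS):
                new_value, step = prior + 1, "S7.5.3"
        if new_value is None:
            continue
        target_dob = rows[pos]["baby_dob"]
        same_delivery = view[(view["mum_ppn"].astype(str) == mum) &
                             (view["baby_dob"] == target_dob) &
                             view["parity"].isna()]
        for _, row in same_delivery.iterrows():
            ledger.correct(str(row["record_id"]), "parity", None,
                           int(new_value), step)
            n_corrected += 1
    return n_corrected


# ---------------------------------------------------------------------------
# Step 8 — parity consistency

@dataclass
class ParityAssessment:
    mum_ppn: str
    count_pregnancies: int
    expected_pregnancies: int | None
    sequence_class: str          # logical | illogical | not_assessable
    outcome: str                 # consistent | missing_unreplaced |
    #                              intervening_births | typo_corrected |
    #                              exclusion | grey_no_change


def _digit_distance_one(a: int, b: int) -> bool:
    sa, sb = str(a), str(b)
    width = max(len(sa), len(sb))
    sa, sb = sa.zfill(width), sb.zfill(width)
    return sum(x != y for x, y in zip(sa, sb)) == 1


def _repair_parity(parities: list) -> tuple[int, int] | None:
    """Search for a unique single-record typo repair.

    A non-missing parity at position ``i`` may be replaced by ``v`` when (a)
    ``v`` differs from the recorded value in exactly one digit, or the
    recorded value is >=10 while its non-missing neighbours are <10, and (b)
    the repaired sequence is strictly increasing with the expected number of
    pregnancies equal to the record count.  When several candidates compete,
    a lone two-digit value among single-digit neighbours is preferred (the
    characteristic stray-digit typo); remaining ambiguity declines the
    repair.  Returns ``(position, value)`` or None.
    """
    n = len(parities)
    nonmiss_idx = [i for i, p in enumerate(parities) if not pd.isna(p)]
    candidates: set[tuple[int, int]] = set()
    outliers: set[tuple[int, int]] = set()
    for i in nonmiss_idx:
        recorded = int(parities[i])
        neighbours = []
        before = [j for j in nonmiss_idx if j < i]
        after = [j for j in nonmiss_idx if j > i]
        if before:
            neighbours.append(int(parities[before[-1]]))
        if after:
            neighbours.append(int(parities[after[0]]))
        allow_any = recorded >= 10 and neighbours and all(v < 10 for v in neighbours)
        for v in range(0, 41):
            if v == recorded:
                continue
            if not (_digit_distance_one(recorded, v) or allow_any):
                continue
            trial = list(parities)
            trial[i] = v
            vals = [int(p) for p in trial if not pd.isna(p)]
            if len(vals) >= 2 and not all(a < b for a, b in zip(vals, vals[1:])):
                continue
            if max(vals) - min(vals) + 1 != n:
                continue
            if allow_any:
                outliers.add((i, v))
            candidates.add((i, v))
    if len(candidates) == 1:
        return candidates.pop()
    if len(candidates) > 1 and len(outliers) == 1:
        return outliers.pop()
    return None


def assess_parity_consistency(perinatal: pd.DataFrame, ledger: FlagLedger
                              ) -> list[ParityAssessment]:
    """Step 8 — compare the number of delivery records against the number
    of pregnancies implied by the parity span, per mother.

    Logical sequences: equal counts are consistent; a shortfall of 1-3
    records suggests intervening births elsewhere; a large span (difference
    >=4, or expected >=10) triggers a conservative single-digit typo-repair
    search.  Illogical sequences meeting the exclusion thresholds (expected
    1 with >=4 records, or expected >=2 with >=2 surplus records) indicate
    fused records of different women and exclude the mother; other
    illogical patterns are quantified but left unchanged.
    """
    assessments: list[ParityAssessment] = []
    view = active_perinatal(perinatal, ledger)
    if view.empty:
        return assessments
    by_mother = _mother_first_rows(view)
    for mum, rows in sorted(by_mother.items()):
        parities = [r["parity"] for r in rows]
        count = len(parities)
        nonmiss = [int(p) for p in parities if not pd.isna(p)]
        if not nonmiss:
            assessments.append(ParityAssessment(
                mum, count, None, "not_assessable", "grey_no_change"))
            continue
        expected = max(nonmiss) - min(nonmiss) + 1
        seq_class = classify_parity_sequence(parities)

        def _attempt_repair(step_id: str) -> bool:
            repair = _repair_parity(parities)
            if repair is None:
                return False
            pos, value = repair
            row = rows[pos]
            old = int(row["parity"])
            targets = view[(view["mum_ppn"].astype(str) == mum) &
                           (view["baby_dob"] == row["baby_dob"]) &
                           (view["parity"] == old)]
            for _, t in targets.iterrows():
                ledger.correct(str(t["record_id"]), "parity", old, value, step_id)
            return True

        if seq_class != "illogical":
            diff = expected - count
            if diff == 0:
                outcome = "consistent"
            elif diff < 0:
                outcome = "missing_unreplaced"
            elif diff <= 3:
                outcome = "intervening_births"
            else:
                outcome = ("typo_corrected" if _attempt_repair("S8.2.4")
                           else "grey_no_change")
            # a large expected span alone (>=10) also warrants a repair search
            if outcome == "intervening_births" and expected >= 10:
                if _attempt_repair("S8.2.4"):
                    outcome = "typo_corrected"
        else:
            if (expected == 1 and count >= 4) or \
                    (expected >= 2 and count - expected >= 2):
                ledger.flag("person", mum, "exclusion", "S8.3.1",
                            reason_code="inconsistent_parity",
                            detail=f"expected {expected}, count {count}, "
                                   f"sequence {nonmiss}")
                outcome = "exclusion"
            elif expected > count and (expected - count >= 4 or expected >= 10):
                outcome = ("typo_corrected" if _attempt_repair("S8.3.2")
                           else "grey_no_change")
            else:
                outcome = "grey_no_change"
        assessments.append(ParityAssessment(mum, count, expected,
                                            seq_class, outcome))
    return assessments


def parity_assessment_frame(assessments: list[ParityAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.mum_ppn, a.count_pregnancies,
          -1 if a.expected_pregnancies is None else a.expected_pregnancies,
          a.sequence_class, a.outcome) for a in assessments],
        columns=["mum_ppn", "count", "expected", "sequence_class", "outcome"],
    )
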