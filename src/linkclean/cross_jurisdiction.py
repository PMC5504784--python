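"""Cross-jurisdiction identifier resolution.

The pharmaceutical-claims ID space (PATID) is related to the state-based
mother IDs (mumPPN) only through probabilistic mapping tables.  After
extracting the links at or above the recommended acceptance weight, four
anomaly patterns are resolved on content data:

* one PATID matching several mumPPNs in one state — a candidate cluster of
  IDs belonging to one woman (a missed state-side link), validated by the
  same interval/parity/YOB/death battery used within states;
* claims supplied after the matched woman's death — the link is disregarded;
* one PATID matching mumPPNs in both states — a candidate cross-state
  woman, validated the same way, with the weaker side disregarded on
  failure;
* one woman (finalPPNmum) matching several PATIDs — checked for consistent
  month/year of birth in the claims and a logical parity sequence.

Accepted clusters and cross-state groupings collapse into ``finalPPNmum``
with precedence CrossID > ClusterID > mumPPN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta

import networkx as nx
import pandas as pd

from .model import FlagLedger, IdentityResolution, ReviewQueue, \
    active_perinatal, active_records
from .perinatal import classify_parity_sequence, _interval_between
from .cross_source import DEATH_ALLOWANCE_DAYS

#: recommended acceptance thresholds for the match weight, per jurisdiction
DEFAULT_THRESHOLDS = {"A": 29.0, "B": 28.0}

#: floor below which candidate matches are not released at all
RELEASE_FLOOR = 17.0


def link_id(patid: str, mum_ppn: str) -> str:
    return f"{patid}|{mum_ppn}"


def extract_recommended_links(mapping: pd.DataFrame,
                              thresholds: dict[str, float] | None = None
                              ) -> pd.DataFrame:
    """Accept links with weight >= the jurisdiction's recommended threshold
    (inclusive); weaker links down to the release floor are kept in a
    separate sub-threshold pool for sensitivity analyses.

    Returns a copy of the mapping table with a ``status`` column
    (``accepted`` / ``sub_threshold``).
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    links = mapping.copy()
    unknown = sorted(set(links["jurisdiction"].astype(str)) - set(thresholds))
    if unknown:
        raise ValueError(f"no threshold configured for jurisdiction(s) {unknown}")
    thr = links["jurisdiction"].astype(str).map(thresholds)
    links["status"] = "sub_threshold"
    links.loc[links["weight"] >= thr, "status"] = "accepted"
    return links


@dataclass
class ClusterDecision:
    group_id: str
    member_ppns: list[str]
    member_patids: list[str]
    status: str                       # accepted | rejected
    rejection_reason: str | None = None
    disregarded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Shared consistency battery (intervals, parity, YOB, service-after-death)

def consistency_battery(member_ppns: list[str],
                        tables: dict[str, pd.DataFrame],
                        ledger: FlagLedger,
                        allowance_days: int = DEATH_ALLOWANCE_DAYS
                        ) -> str | None:
    """Pool the member PPNs' records as if they were one woman and re-run
    the person-level checks.  Returns the first failure reason
    (``exclusion_flag``, ``negative_interval``, ``different_yob``,
    ``inconsistent_parity``, ``service_after_death``) or None when the pool
    is consistent."""
    members = sorted(set(str(p) for p in member_ppns))
    if set(members) & ledger.excluded_persons():
        return "exclusion_flag"

    perinatal = tables.get("perinatal", pd.DataFrame())
    view = active_perinatal(perinatal, ledger) if not perinatal.empty else perinatal
    mine = view[view["mum_ppn"].astype(str).isin(members)] if not view.empty \
        else view

    firsts = mine[mine["birth_order"] == 1].sort_values(
        ["baby_dob", "record_id"]) if not mine.empty else mine
    if not firsts.empty:
        rows = [r for _, r in firsts.iterrows()]
        for prior, nxt in zip(rows, rows[1:]):
            iv = _interval_between(prior, nxt)
            if iv is not None and iv < 0:
                return "negative_interval"

    encounters = tables.get("encounters", pd.DataFrame())
    enc = active_records(encounters, ledger) if not encounters.empty else encounters
    if not mine.empty:
        per_yobs = mine["mother_yob"].dropna().unique()
        if len(per_yobs) > 1:
            return "different_yob"
        pooled = set(int(y) for y in per_yobs)
        if not enc.empty:
            menc = enc[(enc["role"] == "mother") &
                       enc["ppn"].astype(str).isin(members)]
            pooled |= set(int(y) for y in menc["patient_yob"].dropna().unique()
                          if 1900 <= int(y) <= 2014)
        if len(pooled) > 3:
            return "different_yob"

    if not firsts.empty:
        parities = firsts["parity"].tolist()
        nonmiss = [int(p) for p in parities if not pd.isna(p)]
        if classify_parity_sequence(parities) == "illogical" and nonmiss:
            expected = max(nonmiss) - min(nonmiss) + 1
            count = len(parities)
            if (expected == 1 and count >= 4) or \
                    (expected >= 2 and count - expected >= 2):
                return "inconsistent_parity"

    deaths = tables.get("deaths", pd.DataFrame())
    if deaths is not None and not deaths.empty:
        dview = active_records(deaths, ledger)
        dmine = dview[dview["ppn"].astype(str).isin(members)]
        if not dmine.empty:
            dod = dmine["date_of_death"].min()
            limit = dod + timedelta(days=allowance_days)
            if not enc.empty:
                sep = enc.loc[enc["ppn"].astype(str).isin(members),
                              "separation_date"]
                if (sep > limit).any():
                    return "service_after_death"
            if not mine.empty and (mine["baby_dob"] > limit).any():
                return "service_after_death"
    return None


# ---------------------------------------------------------------------------
# Step 17 — clusters of mumPPNs under one PATID (within one state)

def _n_perinatal_records(tables: dict, ppn: str) -> int:
    per = tables.get("perinatal", pd.DataFrame())
    if per.empty:
        return 0
    return int((per["mum_ppn"].astype(str) == ppn).sum())


def detect_patid_clusters(links: pd.DataFrame,
                          tables: dict[str, pd.DataFrame],
                          ledger: FlagLedger,
                          review: ReviewQueue) -> list[ClusterDecision]:
    """Step 17 — within each state, PATIDs matching two or more mumPPNs.

    Connected components of the accepted within-state link graph with more
    than one mumPPN are pre-screened with the consistency battery: a
    consistent component is declared a cluster of IDs belonging to one
    woman; otherwise the single most reliable match (maximum weight; ties
    broken by number of perinatal records, then PPN order) is kept and the
    rest are disregarded with a review-queue entry.
    """
    candidates: list[ClusterDecision] = []
    acc = links[links["status"] == "accepted"]
    n_cluster = 0
    for jur in sorted(set(acc["jurisdiction"].astype(str))):
        sub = acc[acc["jurisdiction"].astype(str) == jur]
        graph = nx.Graph()
        for _, row in sub.iterrows():
            graph.add_edge(("patid", str(row["patid"])),
                           ("ppn", str(row["mum_ppn"])))
        for comp in sorted(nx.connected_components(graph),
                           key=lambda c: sorted(c)):
            ppns = sorted(n for kind, n in comp if kind == "ppn")
            patids = sorted(n for kind, n in comp if kind == "patid")
            if len(ppns) < 2:
                continue
            reason = consistency_battery(ppns, tables, ledger)
            if reason is None:
                n_cluster += 1
                candidates.append(ClusterDecision(
                    f"pre{n_cluster:05d}", ppns, patids, "accepted"))
                continue
            # keep one reliable match per multi-match PATID, drop the rest
            disregarded: list[str] = []
            for patid in patids:
                mine = sub[sub["patid"].astype(str) == patid]
                if len(mine) < 2:
                    continue
                ranked = sorted(
                    mine.itertuples(index=False),
                    key=lambda r: (-float(r.weight),
                                   -_n_perinatal_records(tables, str(r.mum_ppn)),
                                   str(r.mum_ppn)))
                for loser in ranked[1:]:
                    lid = link_id(patid, str(loser.mum_ppn))
                    links.loc[(links["patid"].astype(str) == patid) &
                              (links["mum_ppn"].astype(str) == str(loser.mum_ppn)),
                              "status"] = "disregarded_S17"
                    ledger.flag("record", lid, "disregard_link", "S17.3",
                                reason_code=reason)
                    disregarded.append(lid)
            review.add("S17.3", ppns,
                       f"multi-match PATID group inconsistent ({reason}); "
                       f"kept max-weight links")
            candidates.append(ClusterDecision(
                f"rej{len(candidates):05d}", ppns, patids, "rejected",
                reason, disregarded))
    return [c for c in candidates if c.status == "accepted"]


# ---------------------------------------------------------------------------
# Step 18 — pharmaceutical supply after death

def check_supply_after_death(links: pd.DataFrame, claims: pd.DataFrame,
                             deaths: pd.DataFrame,
                             ledger: FlagLedger) -> list[str]:
    """Step 18 — disregard links whose PATID has a claim supplied strictly
    after the matched woman's death."""
    disregarded: list[str] = []
    if claims is None or claims.empty or deaths is None or deaths.empty:
        return disregarded
    dview = active_records(deaths, ledger)
    death_date = dview.groupby(dview["ppn"].astype(str))["date_of_death"].min()
    last_supply = claims.groupby(claims["patid"].astype(str))["date_of_supply"].max()
    acc = links[links["status"] == "accepted"]
    for row in acc.sort_values(["patid", "mum_ppn"]).itertuples(index=False):
        ppn, patid = str(row.mum_ppn), str(row.patid)
        if ppn not in death_date.index or patid not in last_supply.index:
            continue
        if last_supply.loc[patid] > death_date.loc[ppn]:
            links.loc[(links["patid"].astype(str) == patid) &
                      (links["mum_ppn"].astype(str) == ppn),
                      "status"] = "disregarded_S18"
            ledger.flag("record", link_id(patid, ppn), "disregard_link",
                        "S18.2", reason_code="supply_after_death",
                        detail=f"supply {last_supply.loc[patid].date()} after "
                               f"death {death_date.loc[ppn].date()}")
            disregarded.append(link_id(patid, ppn))
    return disregarded


# ---------------------------------------------------------------------------
# Step 19 — validate clusters

def validate_clusters(clusters: list[ClusterDecision],
                      links: pd.DataFrame,
                      tables: dict[str, pd.DataFrame],
                      ledger: FlagLedger) -> list[ClusterDecision]:
    """Step 19 — assign ClusterIDs and re-run the consistency battery with
    inherited death/exclusion state.  A failing cluster excludes all member
    mumPPNs and disregards the associated links."""
    decisions: list[ClusterDecision] = []
    for i, cand in enumerate(sorted(clusters, key=lambda c: c.member_ppns), 1):
        cid = f"C{i:05d}"
        reason = consistency_battery(cand.member_ppns, tables, ledger)
        if reason is None:
            decisions.append(ClusterDecision(cid, cand.member_ppns,
                                             cand.member_patids, "accepted"))
            continue
        disregarded = []
        for ppn in cand.member_ppns:
            ledger.flag("person", ppn, "exclusion", "S19.4",
                        reason_code=reason, detail=f"cluster {cid} rejected")
        mask = links["mum_ppn"].astype(str).isin(cand.member_ppns) & \
            (links["status"] == "accepted")
        for row in links[mask].itertuples(index=False):
            lid = link_id(str(row.patid), str(row.mum_ppn))
            ledger.flag("record", lid, "disregard_link", "S19.4",
                        reason_code=reason)
            disregarded.append(lid)
        links.loc[mask, "status"] = "disregarded_S19"
        decisions.append(ClusterDecision(cid, cand.member_ppns,
                                         cand.member_patids, "rejected",
                                         reason, disregarded))
    return decisions


# ---------------------------------------------------------------------------
# Step 20 — cross-state women

def resolve_cross_state(links: pd.DataFrame,
                        tables: dict[str, pd.DataFrame],
                        ledger: FlagLedger,
                        review: ReviewQueue) -> list[ClusterDecision]:
    """Step 20 — PATIDs matching mumPPNs in both jurisdictions.

    CrossIDs are assigned over connected components of the accepted link
    graph that contain a cross-matching PATID, so chained networks (one PPN
    to two PATIDs to three PPNs in the other state) resolve to a single
    cross-state woman.  A component failing the consistency battery keeps
    the stronger state's links; the weaker state's cross links are
    disregarded (on an exclusion flag, the flagged state loses).
    """
    decisions: list[ClusterDecision] = []
    acc = links[links["status"] == "accepted"]
    if acc.empty:
        return decisions
    jur_of_ppn = {str(r.mum_ppn): str(r.jurisdiction)
                  for r in acc.itertuples(index=False)}
    by_patid = acc.groupby(acc["patid"].astype(str))["jurisdiction"]
    cross_patids = {p for p, g in by_patid if g.astype(str).nunique() > 1}
    if not cross_patids:
        return decisions

    graph = nx.Graph()
    for row in acc.itertuples(index=False):
        graph.add_edge(("patid", str(row.patid)), ("ppn", str(row.mum_ppn)),
                       weight=float(row.weight))
    comps = [c for c in nx.connected_components(graph)
             if any(kind == "patid" and name in cross_patids
                    for kind, name in c)]
    for i, comp in enumerate(sorted(comps, key=lambda c: sorted(c)), 1):
        xid = f"X{i:05d}"
        ppns = sorted(n for kind, n in comp if kind == "ppn")
        patids = sorted(n for kind, n in comp if kind == "patid")
        reason = consistency_battery(ppns, tables, ledger)
        if reason is None:
            decisions.append(ClusterDecision(xid, ppns, patids, "accepted"))
            continue
        # choose the state whose cross links to disregard
        cross_links = acc[acc["patid"].astype(str).isin(set(patids) & cross_patids) &
                          acc["mum_ppn"].astype(str).isin(ppns)]
        if reason == "exclusion_flag":
            excluded = sorted(set(ppns) & ledger.excluded_persons())
            lose_states = sorted({jur_of_ppn[p] for p in excluded})
            lose = lose_states[0]
        else:
            review_hist = review.targets_for_step("S")
            def _state_key(state: str):
                sl = cross_links[cross_links["jurisdiction"].astype(str) == state]
                return (float(sl["weight"].min()) if not sl.empty else float("inf"),
                        -int(bool(set(sl["mum_ppn"].astype(str)) & review_hist)),
                        sum(_n_perinatal_records(tables, p)
                            for p in set(sl["mum_ppn"].astype(str))),
                        state)
            states = sorted(set(cross_links["jurisdiction"].astype(str)))
            lose = min(states, key=_state_key)
        disregarded = []
        mask = links["patid"].astype(str).isin(set(patids) & cross_patids) & \
            (links["jurisdiction"].astype(str) == lose) & \
            (links["status"] == "accepted")
        for row in links[mask].itertuples(index=False):
            lid = link_id(str(row.patid), str(row.mum_ppn))
            ledger.flag("record", lid, "disregard_link", "S20.12",
                        reason_code=reason,
                        detail=f"cross group {xid} rejected; state {lose} "
                               f"side disregarded")
            disregarded.append(lid)
        links.loc[mask, "status"] = "disregarded_S20"
        decisions.append(ClusterDecision(xid, ppns, patids, "rejected",
                                         reason, disregarded))
    return decisions


# ---------------------------------------------------------------------------
# Step 21 — finalPPNmum

def integrate_final_ppn(mum_ppns: list[str], ledger: FlagLedger,
                        cluster_decisions: list[ClusterDecision],
                        cross_decisions: list[ClusterDecision]
                        ) -> IdentityResolution:
    """Step 21 — collapse accepted CrossIDs and ClusterIDs into one person
    number per woman, with precedence CrossID > ClusterID > mumPPN."""
    res = IdentityResolution()
    for dec in cross_decisions:
        if dec.status == "accepted":
            for ppn in dec.member_ppns:
                res.cross_assignments[ppn] = dec.group_id
    for dec in cluster_decisions:
        if dec.status != "accepted":
            continue
        xids = {res.cross_assignments.get(p) for p in dec.member_ppns}
        if len(xids) > 1 and None in xids:
            raise RuntimeError(
                f"cluster {dec.group_id} straddles an accepted cross-state "
                f"group; decisions are not nested")
        if len(xids - {None}) > 1:
            raise RuntimeError(
                f"cluster {dec.group_id} members map to different CrossIDs")
        for ppn in dec.member_ppns:
            res.cluster_assignments[ppn] = dec.group_id
    res.resolve(mum_ppns)
    return res


# ---------------------------------------------------------------------------
# Step 22 — women with multiple PATIDs; final cohort

@dataclass
class FinalCohort:
    resolution: IdentityResolution
    multi_patid_women: list[str]
    excluded_women: list[str]
    cohort: pd.DataFrame                 # final_ppn_mum, member_ppns, excluded
    claims_extract: pd.DataFrame


def check_multi_patid(links: pd.DataFrame, claims: pd.DataFrame,
                      perinatal: pd.DataFrame,
                      resolution: IdentityResolution,
                      ledger: FlagLedger) -> FinalCohort:
    """Step 22 — women (finalPPNmum) matched to two or more PATIDs.

    Links of excluded women are removed first.  The remaining multi-PATID
    women are checked for consistent month and year of birth across their
    claims and a logical parity sequence; failures are excluded and their
    links removed.  Claims for the final cohort are then extracted.
    """
    excluded = ledger.excluded_persons()
    final_of = resolution.final_ppn
    # 22.1 — remove links of excluded women
    mask_excl = links["mum_ppn"].astype(str).isin(excluded) & \
        (links["status"] == "accepted")
    for row in links[mask_excl].itertuples(index=False):
        ledger.flag("record", link_id(str(row.patid), str(row.mum_ppn)),
                    "disregard_link", "S22.1", reason_code="excluded_woman")
    links.loc[mask_excl, "status"] = "disregarded_S22"

    acc = links[links["status"] == "accepted"].copy()
    acc["final_ppn"] = acc["mum_ppn"].astype(str).map(
        lambda p: final_of.get(p, p))
    multi: list[str] = []
    newly_excluded: list[str] = []
    for fppn, grp in acc.groupby("final_ppn", sort=True):
        patids = sorted(set(grp["patid"].astype(str)))
        if len(patids) < 2:
            continue
        my_claims = claims[claims["patid"].astype(str).isin(patids)] \
            if claims is not None and not claims.empty else pd.DataFrame()
        inconsistent = False
        if not my_claims.empty:
            yobs = my_claims["year_of_birth"].dropna().nunique()
            mobs = my_claims["month_of_birth"].dropna().nunique()
            inconsistent = yobs > 1 or mobs > 1
        if not inconsistent and perinatal is not None and not perinatal.empty:
            members = sorted(set(grp["mum_ppn"].astype(str)))
            view = active_perinatal(perinatal, ledger)
            firsts = view[view["mum_ppn"].astype(str).isin(members) &
                          (view["birth_order"] == 1)]
            firsts = firsts.sort_values(["baby_dob", "record_id"])
            if classify_parity_sequence(firsts["parity"]) == "illogical":
                inconsistent = True
        if not inconsistent:
            multi.append(str(fppn))
            continue
        members = sorted(set(grp["mum_ppn"].astype(str)))
        for ppn in members:
            ledger.flag("person", ppn, "exclusion", "S22.2",
                        reason_code="multi_patid_inconsistent",
                        detail=f"finalPPNmum {fppn} with PATIDs {patids}")
        newly_excluded.append(str(fppn))
        mask = links["mum_ppn"].astype(str).isin(members) & \
            (links["status"] == "accepted")
        for row in links[mask].itertuples(index=False):
            ledger.flag("record", link_id(str(row.patid), str(row.mum_ppn)),
                        "disregard_link", "S22.2",
                        reason_code="multi_patid_inconsistent")
        links.loc[mask, "status"] = "disregarded_S22"

    # 22.3 — final cohort and claims extract
    excluded = ledger.excluded_persons()
    rows = []
    members_of: dict[str, list[str]] = {}
    for ppn, fppn in sorted(final_of.items()):
        members_of.setdefault(fppn, []).append(ppn)
    for fppn, members in sorted(members_of.items()):
        is_excl = bool(set(members) & excluded)
        rows.append((fppn, ";".join(sorted(members)), int(is_excl)))
    cohort = pd.DataFrame(rows, columns=["final_ppn_mum", "member_ppns",
                                         "excluded"])
    keep_patids = set(
        links.loc[links["status"] == "accepted", "patid"].astype(str))
    claims_extract = claims[claims["patid"].astype(str).isin(keep_patids)] \
        if claims is not None and not claims.empty else pd.DataFrame()
    return FinalCohort(resolution, multi, newly_excluded, cohort,
                       claims_extract.copy())
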