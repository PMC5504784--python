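"""Link extraction thresholds, cluster/cross-state resolution, final person
number integration, and multi-PATID checks."""

import numpy as np
import pandas as pd
import pytest

from linkclean.cross_jurisdiction import (check_multi_patid,
                                          check_supply_after_death,
                                          consistency_battery,
                                          detect_patid_clusters,
                                          extract_recommended_links,
                                          integrate_final_ppn, link_id,
                                          resolve_cross_state,
                                          validate_clusters)
from linkclean.model import FlagLedger, ReviewQueue

from conftest import death_row, empty_table, make_table, perinatal_row


def mapping_table(links):
    return make_table("mapping", [
        {"patid": p, "mum_ppn": m, "jurisdiction": j, "weight": w}
        for p, m, j, w in links])


EMPTY = {"perinatal": empty_table("perinatal"),
         "encounters": empty_table("encounters"),
         "deaths": empty_table("deaths")}


def run_resolution(links, tables=None, claims=None, perinatal=None):
    """Drive the S17-S22 chain and return everything a test could inspect."""
    tables = tables or EMPTY
    ledger, review = FlagLedger(), ReviewQueue()
    clusters = detect_patid_clusters(links, tables, ledger, review)
    check_supply_after_death(links, claims, tables.get("deaths"), ledger)
    cluster_dec = validate_clusters(clusters, links, tables, ledger)
    cross_dec = resolve_cross_state(links, tables, ledger, review)
    ppns = sorted(set(links["mum_ppn"].astype(str)))
    res = integrate_final_ppn(ppns, ledger, cluster_dec, cross_dec)
    final = check_multi_patid(
        links, claims if claims is not None else empty_table("claims"),
        perinatal if perinatal is not None else tables["perinatal"],
        res, ledger)
    return res, cluster_dec, cross_dec, final, ledger, review


class TestExtraction:
    def test_thresholds_inclusive_per_jurisdiction(self):
        links = extract_recommended_links(mapping_table([
            ("T1", "MA1", "A", 28.5),
            ("T2", "MB1", "B", 28.0),
            ("T3", "MA2", "A", 29.0),
            ("T4", "MB2", "B", 17.0),
        ]))
        status = dict(zip(links["patid"], links["status"]))
        assert status == {"T1": "sub_threshold", "T2": "accepted",
                          "T3": "accepted", "T4": "sub_threshold"}

    def test_sub_threshold_pool_preserved_down_to_17(self):
        links = extract_recommended_links(mapping_table([
            ("T1", "MA1", "A", 17.0), ("T2", "MA2", "A", 24.9)]))
        assert (links["status"] == "sub_threshold").all()
        assert len(links) == 2

    def test_unknown_jurisdiction_rejected(self):
        with pytest.raises(ValueError):
            extract_recommended_links(mapping_table([("T1", "M1", "C", 30.0)]))


def _two_women(yob2=1975, dob2="2006-06-01", parity2=0):
    """Perinatal data for two candidate cluster members."""
    return make_table("perinatal", [
        perinatal_row("R1", "M1", "B1", "2005-01-01", mother_yob=1975),
        perinatal_row("R2", "M2", "B2", dob2, mother_yob=yob2,
                      parity=parity2),
    ])


class TestBattery:
    def test_consistent_members_pass(self):
        tables = dict(EMPTY, perinatal=_two_women(parity2=1))
        assert consistency_battery(["M1", "M2"], tables, FlagLedger()) is None

    def test_exclusion_flag_inherited(self):
        ledger = FlagLedger()
        ledger.flag("person", "M2", "exclusion", "S6.4")
        assert consistency_battery(["M1", "M2"], EMPTY, ledger) == \
            "exclusion_flag"

    def test_pooled_negative_interval_detected(self):
        # M2 delivers 30 days after M1 at 39 weeks gestation: impossible
        tables = dict(EMPTY, perinatal=_two_women(dob2="2005-01-31"))
        assert consistency_battery(["M1", "M2"], tables, FlagLedger()) == \
            "negative_interval"

    def test_different_yob_detected(self):
        tables = dict(EMPTY, perinatal=_two_women(yob2=1988))
        assert consistency_battery(["M1", "M2"], tables, FlagLedger()) == \
            "different_yob"

    def test_pooled_illogical_parity_detected(self):
        rows = [perinatal_row(f"R{i}", f"M{1 + i % 2}", f"B{i}",
                              f"20{a:02d}-01-01", parity=p)
                for i, (a, p) in enumerate([(4, 0), (5, 1), (6, 0), (7, 1)])]
        tables = dict(EMPTY, perinatal=make_table("perinatal", rows))
        assert consistency_battery(["M1", "M2"], tables, FlagLedger()) == \
            "inconsistent_parity"

    def test_service_after_pooled_death_detected(self):
        per = _two_women(parity2=1)
        deaths = make_table("deaths", [death_row("D1", "M1", "2005-06-01")])
        tables = dict(EMPTY, perinatal=per, deaths=deaths)
        assert consistency_battery(["M1", "M2"], tables, FlagLedger()) == \
            "service_after_death"


class TestClusters:
    def test_consistent_multimatch_becomes_accepted_cluster(self):
        links = extract_recommended_links(mapping_table([
            ("T1", "M1", "A", 35.0), ("T1", "M2", "A", 30.0)]))
        tables = dict(EMPTY, perinatal=_two_women(parity2=1))
        res, cluster_dec, *_ = run_resolution(links, tables)
        assert [d.status for d in cluster_dec] == ["accepted"]
        assert res.cluster_assignments["M1"] == res.cluster_assignments["M2"]
        assert res.final_ppn["M1"] == res.final_ppn["M2"]

    def test_inconsistent_multimatch_keeps_max_weight_link(self):
        links = extract_recommended_links(mapping_table([
            ("T1", "M1", "A", 35.0), ("T1", "M2", "A", 29.2)]))
        tables = dict(EMPTY, perinatal=_two_women(yob2=1990))
        res, cluster_dec, _, _, ledger, review = run_resolution(links, tables)
        assert cluster_dec == []
        assert links.loc[links["mum_ppn"] == "M2", "status"].iloc[0] == \
            "disregarded_S17"
        assert link_id("T1", "M2") in ledger.disregarded_links()
        assert review.items and review.items[0]["step_id"] == "S17.3"
        assert res.final_ppn["M1"] == "M1"

    def test_rejected_cluster_excludes_members(self):
        # consistent at pre-screen is required for a cluster, so force a
        # rejection through an exclusion flag arriving before validation
        links = extract_recommended_links(mapping_table([
            ("T1", "M1", "A", 35.0), ("T1", "M2", "A", 30.0)]))
        tables = dict(EMPTY, perinatal=_two_women(parity2=1))
        ledger, review = FlagLedger(), ReviewQueue()
        clusters = detect_patid_clusters(links, tables, ledger, review)
        ledger.flag("person", "M2", "exclusion", "S15.4")
        decisions = validate_clusters(clusters, links, tables, ledger)
        assert decisions[0].status == "rejected"
        assert decisions[0].rejection_reason == "exclusion_flag"
        assert ledger.excluded_persons() >= {"M1", "M2"}
        assert (links["status"] == "disregarded_S19").all()


class TestSupplyAfterDeath:
    def _links(self):
        return extract_recommended_links(mapping_table([
            ("T1", "M1", "A", 35.0)]))

    def _claims(self, supply):
        return make_table("claims", [
            {"claim_id": "C1", "patid": "T1", "date_of_supply": supply,
             "item_code": "X", "month_of_birth": 1, "year_of_birth": 1980}])

    def test_supply_after_death_disregards_link(self):
        links = self._links()
        deaths = make_table("deaths", [death_row("D1", "M1", "2011-04-01")])
        out = check_supply_after_death(links, self._claims("2011-05-01"),
                                       deaths, FlagLedger())
        assert out == [link_id("T1", "M1")]
        assert (links["status"] == "disregarded_S18").all()

    def test_supply_on_death_date_kept(self):
        links = self._links()
        deaths = make_table("deaths", [death_row("D1", "M1", "2011-05-01")])
        assert check_supply_after_death(links, self._claims("2011-05-01"),
                                        deaths, FlagLedger()) == []

    def test_no_death_record_kept(self):
        links = self._links()
        assert check_supply_after_death(links, self._claims("2011-05-01"),
                                        empty_table("deaths"),
                                        FlagLedger()) == []


class TestCrossState:
    def test_footnote_network_collapses_to_one_cross_id(self):
        # 1 A-PPN matched by 2 PATIDs which also match 3 B-PPNs
        rows = [perinatal_row("RA", "MA1", "BA1", "2004-01-01",
                              mother_yob=1979)]
        for i in (1, 2, 3):
            rows.append(perinatal_row(f"RB{i}", f"MB{i}", f"BB{i}",
                                      f"200{4 + i}-06-01", jur="B",
                                      mother_yob=1979, parity=i))
        tables = dict(EMPTY, perinatal=make_table("perinatal", rows))
        links = extract_recommended_links(mapping_table([
            ("T1", "MA1", "A", 31.0), ("T2", "MA1", "A", 30.0),
            ("T1", "MB1", "B", 30.0), ("T2", "MB2", "B", 29.0),
            ("T2", "MB3", "B", 28.5),
        ]))
        res, _, cross_dec, *_ = run_resolution(links, tables)
        accepted = [d for d in cross_dec if d.status == "accepted"]
        assert len(accepted) == 1
        assert accepted[0].member_ppns == ["MA1", "MB1", "MB2", "MB3"]
        finals = {res.final_ppn[p] for p in ("MA1", "MB1", "MB2", "MB3")}
        assert finals == {accepted[0].group_id}

    def test_rejected_cross_pair_disregards_lower_weight_side(self):
        tables = dict(EMPTY, perinatal=make_table("perinatal", [
            perinatal_row("R1", "MA1", "B1", "2005-01-01", mother_yob=1975),
            perinatal_row("R2", "MB1", "B2", "2006-01-01", jur="B",
                          mother_yob=1990),
        ]))
        links = extract_recommended_links(mapping_table([
            ("T1", "MA1", "A", 35.0), ("T1", "MB1", "B", 28.0)]))
        res, _, cross_dec, _, ledger, _ = run_resolution(links, tables)
        assert cross_dec[0].status == "rejected"
        assert cross_dec[0].rejection_reason == "different_yob"
        assert link_id("T1", "MB1") in ledger.disregarded_links()
        assert links.loc[links["mum_ppn"] == "MB1", "status"].iloc[0] == \
            "disregarded_S20"
        assert res.final_ppn["MA1"] == "MA1"
        assert res.final_ppn["MB1"] == "MB1"

    def test_consistent_cross_pair_accepted(self):
        tables = dict(EMPTY, perinatal=make_table("perinatal", [
            perinatal_row("R1", "MA1", "B1", "2005-01-01", mother_yob=1975),
            perinatal_row("R2", "MB1", "B2", "2007-01-01", jur="B",
                          mother_yob=1975, parity=1),
        ]))
        links = extract_recommended_links(mapping_table([
            ("T1", "MA1", "A", 35.0), ("T1", "MB1", "B", 28.4)]))
        res, _, cross_dec, *_ = run_resolution(links, tables)
        assert cross_dec[0].status == "accepted"
        assert res.final_ppn["MA1"] == res.final_ppn["MB1"]


class TestIntegration:
    def test_hierarchy_cross_beats_cluster(self):
        res = integrate_final_ppn(["M1"], FlagLedger(), [], [])
        assert res.final_ppn == {"M1": "M1"}

    def test_component_count_two_clusters_plus_singletons(self):
        # 10 PPNs: two accepted clusters of 3, four singletons -> 6 IDs
        links = extract_recommended_links(mapping_table(
            [("T1", f"M{i}", "A", 30.0 + i) for i in (1, 2, 3)] +
            [("T2", f"M{i}", "A", 30.0 + i) for i in (4, 5, 6)] +
            [(f"T{i}", f"M{i}", "A", 35.0) for i in (7, 8, 9, 10)]))
        rows = [perinatal_row(f"R{i}", f"M{i}", f"B{i}",
                              f"20{i:02d}-01-01", mother_yob=1970,
                              parity={1: 0, 2: 1, 3: 2, 4: 0, 5: 1, 6: 2}
                              .get(i, 0))
                for i in range(1, 11)]
        tables = dict(EMPTY, perinatal=make_table("perinatal", rows))
        res, cluster_dec, *_ = run_resolution(links, tables)
        assert sum(d.status == "accepted" for d in cluster_dec) == 2
        assert len(set(res.final_ppn.values())) == 6


def transitive_closure_oracle(edges, nodes):
    """Brute-force connected components by repeated relaxation."""
    label = {n: n for n in nodes}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            lo = min(label[a], label[b])
            for n in (a, b):
                if label[n] != lo:
                    label[n] = lo
                    changed = True
        # propagate through shared labels
        for n in nodes:
            if label[label[n]] != label[n]:
                label[n] = label[label[n]]
                changed = True
    return label


def test_final_ppn_components_match_transitive_closure_oracle():
    """200 random bipartite PATID-PPN graphs (<=50 nodes): two PPNs share a
    finalPPNmum exactly when the accepted-link graph connects them."""
    rng = np.random.default_rng(42)
    for trial in range(200):
        n_patid = int(rng.integers(1, 13))
        n_ppn = int(rng.integers(1, 13))
        patids = [f"T{i}" for i in range(n_patid)]
        ppns = [f"M{i}" for i in range(n_ppn)]
        n_edges = int(rng.integers(1, 2 * max(n_patid, n_ppn)))
        edges = sorted({(patids[int(rng.integers(n_patid))],
                         ppns[int(rng.integers(n_ppn))])
                        for _ in range(n_edges)})
        links = extract_recommended_links(mapping_table(
            [(p, m, "A", 30.0) for p, m in edges]))
        res, *_ = run_resolution(links)
        label = transitive_closure_oracle(edges, set(patids) | set(ppns))
        used_ppns = sorted({m for _, m in edges})
        for a in used_ppns:
            for b in used_ppns:
                same_oracle = label[a] == label[b]
                same_final = res.final_ppn[a] == res.final_ppn[b]
                assert same_final == same_oracle, (trial, a, b, edges)


def test_link_status_conservation():
    links = extract_recommended_links(mapping_table([
        ("T1", "M1", "A", 35.0), ("T1", "M2", "A", 29.2),
        ("T2", "M3", "A", 20.0), ("T3", "M4", "B", 28.6)]))
    tables = dict(EMPTY, perinatal=_two_women(yob2=1990))
    run_resolution(links, tables)
    assert set(links["status"]) <= {
        "accepted", "sub_threshold", "disregarded_S17", "disregarded_S18",
        "disregarded_S19", "disregarded_S20", "disregarded_S22"}
    assert len(links) == 4   # no link silently dropped


class TestMultiPatid:
    def _fixture(self, yob2):
        per = make_table("perinatal", [
            perinatal_row("R1", "M1", "B1", "2005-01-01", mother_yob=1980)])
        links = extract_recommended_links(mapping_table([
            ("T1", "M1", "A", 35.0), ("T2", "M1", "A", 30.0)]))
        claims = make_table("claims", [
            {"claim_id": "C1", "patid": "T1", "date_of_supply": "2006-01-01",
             "item_code": "X", "month_of_birth": 3, "year_of_birth": 1980},
            {"claim_id": "C2", "patid": "T2", "date_of_supply": "2006-02-01",
             "item_code": "X", "month_of_birth": 3, "year_of_birth": yob2},
        ])
        return per, links, claims

    def test_inconsistent_claim_yob_excludes(self):
        per, links, claims = self._fixture(1981)
        res, _, _, final, ledger, _ = run_resolution(
            links, dict(EMPTY, perinatal=per), claims, per)
        assert "M1" in ledger.excluded_persons()
        assert ledger.exclusion_step("M1") == "S22.2"
        assert (links["status"] == "disregarded_S22").all()
        assert final.claims_extract.empty

    def test_consistent_multi_patid_woman_counted(self):
        per, links, claims = self._fixture(1980)
        res, _, _, final, ledger, _ = run_resolution(
            links, dict(EMPTY, perinatal=per), claims, per)
        assert final.multi_patid_women == ["M1"]
        assert not ledger.excluded_persons()
        assert len(final.claims_extract) == 2
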