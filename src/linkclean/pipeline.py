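"""Orchestration of the 22-step cleaning protocol.

Steps run in protocol order with apply-before-next semantics: every step
sees views of the source tables filtered by the flags and corrections of all
prior steps.  Person-level exclusions are propagated through the
mother-child family graph after each person-level step.  Data
inconsistencies are findings, never process failures — the pipeline always
completes on schema-valid input and reports what it found.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from . import cross_jurisdiction as xj
from . import cross_source as xs
from . import perinatal as peri
from . import uniqueness as uniq
from .model import (FlagLedger, IdentityResolution, ReviewQueue,
                    active_perinatal, active_records, propagate_exclusions)
from .synth import DEFAULT_HYSTERECTOMY_CODES

log = logging.getLogger("linkclean")

#: execution order and hard dependencies between steps
STEP_ORDER = [f"S{i}" for i in range(1, 23)]
STEP_DEPENDENCIES = {
    "S3": ["S1"],
    "S7": ["S5", "S6"],
    "S8": ["S5", "S6", "S7"],
    "S14": ["S9"],
    "S19": ["S17"],
    "S20": ["S19"],
    "S21": ["S19", "S20"],
    "S22": ["S21"],
}


@dataclass
class PipelineConfig:
    """Constants and switches for a pipeline run.

    Defaults are the protocol's published values: acceptance weights 29 (A)
    and 28 (B), valid year-of-birth windows 1920-2014 (babies) and
    1900-2014 (mothers), the 20-week / 40-week day bounds and the 3-day
    administrative death allowance.
    """

    thresholds: dict = field(default_factory=lambda: dict(xj.DEFAULT_THRESHOLDS))
    hysterectomy_codes: list = field(
        default_factory=lambda: list(DEFAULT_HYSTERECTOMY_CODES))
    baby_yob_valid: tuple = xs.BABY_YOB_VALID
    mother_yob_valid: tuple = xs.MOTHER_YOB_VALID
    death_allowance_days: int = xs.DEATH_ALLOWANCE_DAYS
    enabled_steps: list = field(default_factory=lambda: list(STEP_ORDER))

    def __post_init__(self) -> None:
        enabled = set(self.enabled_steps)
        for step, deps in STEP_DEPENDENCIES.items():
            if step in enabled:
                missing = [d for d in deps if d not in enabled]
                if missing:
                    raise ValueError(
                        f"step {step} requires {missing} to be enabled")


@dataclass
class StepReport:
    step_id: str
    n_flags: dict
    n_corrections: int
    n_review: int
    runtime_s: float
    notes: str = ""


@dataclass
class PipelineResult:
    ledger: FlagLedger
    review: ReviewQueue
    resolution: IdentityResolution
    reports: list[StepReport]
    links: pd.DataFrame | None
    tabulation: object | None
    parity: list
    cluster_decisions: list
    cross_decisions: list
    final: object | None


def _diff_counts(ledger: FlagLedger, start_flags: int) -> dict:
    counts: dict[str, int] = {}
    for e in ledger.entries[start_flags:]:
        counts[e.flag] = counts.get(e.flag, 0) + 1
    return counts


def run_pipeline(tables: dict[str, pd.DataFrame],
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run steps 1-22 on the loaded tables.

    Steps whose tables are absent are skipped with a notice (mirroring
    checks that apply in one jurisdiction only).  Source frames are never
    modified; all outcomes live in the returned ledger, review queue,
    link-status table and identity resolution.
    """
    config = config or PipelineConfig()
    enabled = set(config.enabled_steps)
    ledger = FlagLedger()
    review = ReviewQueue()
    reports: list[StepReport] = []

    perinatal = tables.get("perinatal", pd.DataFrame())
    encounters = tables.get("encounters", pd.DataFrame())
    deaths = tables.get("deaths", pd.DataFrame())
    congenital = tables.get("congenital")
    claims = tables.get("claims")
    mapping = tables.get("mapping")

    tabulation = None
    parity_assessments: list = []
    links = None
    cluster_decisions: list = []
    cross_decisions: list = []
    final = None
    resolution = IdentityResolution()

    def report(step_id, fn, notes=""):
        if step_id not in enabled:
            return None
        n_flags0, n_corr0, n_rev0 = (len(ledger.entries),
                                     len(ledger.corrections),
                                     len(review.items))
        t0 = time.perf_counter()
        out = fn()
        rep = StepReport(step_id, _diff_counts(ledger, n_flags0),
                         len(ledger.corrections) - n_corr0,
                         len(review.items) - n_rev0,
                         time.perf_counter() - t0, notes)
        reports.append(rep)
        log.info("%s: flags=%s corrections=%d review=%d (%.2fs)",
                 step_id, rep.n_flags, rep.n_corrections, rep.n_review,
                 rep.runtime_s)
        return out

    def propagate():
        propagate_exclusions(perinatal, ledger)

    # -- uniqueness of records (S1-S3) --------------------------------------
    def s1():
        for kind, df in [("perinatal", perinatal), ("encounters", encounters),
                         ("deaths", deaths)]:
            if not df.empty:
                uniq.find_identical_duplicates(df, kind, ledger)
        if not deaths.empty:
            uniq.find_partial_death_duplicates(deaths, encounters, ledger,
                                               review)
    report("S1", s1)

    def s2():
        offenders, skipped = uniq.check_death_registration_completeness(deaths)
        if skipped:
            log.info("S2: skipped for jurisdiction(s) without a "
                     "causes-of-death stream: %s", skipped)
        return offenders
    cod_orphans = report("S2", s2)

    def s3():
        uniq.check_baby_ppn_uniqueness(perinatal, ledger, review)
        propagate()
    report("S3", s3)

    # -- perinatal consistency (S4-S8) --------------------------------------
    def s4():
        return peri.tabulate_birthweight_gestation(
            active_perinatal(perinatal, ledger))
    tabulation = report("S4", s4)

    report("S5", lambda: peri.validate_birth_order(perinatal, ledger, review))

    def s6():
        peri.check_pregnancy_intervals(perinatal, ledger)
        propagate()
    report("S6", s6)

    report("S7", lambda: peri.impute_missing_parity(perinatal, ledger))

    def s8():
        out = peri.assess_parity_consistency(perinatal, ledger)
        propagate()
        return out
    parity_assessments = report("S8", s8) or []

    # -- cross-source consistency (S9-S16) ----------------------------------
    if not encounters.empty:
        report("S9", lambda: xs.reconcile_baby_dob(
            perinatal, encounters, ledger, review, config.baby_yob_valid))

    if congenital is not None and not congenital.empty:
        def s10():
            xs.check_congenital_consistency(perinatal, congenital, ledger,
                                            review)
            propagate()
        report("S10", s10)
    elif "S10" in enabled:
        log.info("S10: skipped, no congenital table supplied")

    def s11():
        xs.check_mother_yob(perinatal, encounters, ledger,
                            config.mother_yob_valid)
        propagate()
    report("S11", s11)

    def s12():
        xs.check_mother_sex(perinatal, encounters, ledger,
                            config.mother_yob_valid)
        propagate()
    report("S12", s12)

    def s13():
        if not config.hysterectomy_codes:
            log.info("S13: skipped, empty hysterectomy code list")
            return
        xs.check_birth_after_hysterectomy(perinatal, encounters,
                                          config.hysterectomy_codes, ledger)
        propagate()
    report("S13", s13)

    def s14():
        xs.check_dob_after_discharge(perinatal, encounters, ledger)
        propagate()
    report("S14", s14)

    def s15():
        xs.check_service_after_death(perinatal, encounters, deaths, ledger,
                                     config.death_allowance_days)
        propagate()
    report("S15", s15)

    report("S16", lambda: xs.check_admission_after_discharge(encounters,
                                                             ledger))

    # -- cross-jurisdiction resolution (S17-S22) -----------------------------
    if mapping is not None and not mapping.empty:
        xtables = {"perinatal": perinatal, "encounters": encounters,
                   "deaths": deaths}
        links = xj.extract_recommended_links(mapping, config.thresholds)

        clusters: list = []

        def s17():
            nonlocal clusters
            clusters = xj.detect_patid_clusters(links, xtables, ledger, review)
        report("S17", s17)

        report("S18", lambda: xj.check_supply_after_death(
            links, claims, deaths, ledger))

        def s19():
            nonlocal cluster_decisions
            cluster_decisions = xj.validate_clusters(clusters, links,
                                                     xtables, ledger)
            propagate()
        report("S19", s19)

        def s20():
            nonlocal cross_decisions
            cross_decisions = xj.resolve_cross_state(links, xtables, ledger,
                                                     review)
        report("S20", s20)

        def s21():
            nonlocal resolution
            ppns = sorted(set(perinatal["mum_ppn"].astype(str)) |
                          set(mapping["mum_ppn"].astype(str)))
            resolution = xj.integrate_final_ppn(ppns, ledger,
                                                cluster_decisions,
                                                cross_decisions)
        report("S21", s21)

        def s22():
            nonlocal final
            final = xj.check_multi_patid(links, claims, perinatal,
                                         resolution, ledger)
            propagate()
        report("S22", s22)
    else:
        if enabled & {"S17", "S18", "S19", "S20", "S21", "S22"}:
            log.info("S17-S22: skipped, no mapping table supplied")
        if not perinatal.empty:
            resolution.resolve(sorted(set(perinatal["mum_ppn"].astype(str))))

    return PipelineResult(ledger, review, resolution, reports, links,
                          tabulation, parity_assessments, cluster_decisions,
                          cross_decisions, final)


def summarize(result: PipelineResult) -> pd.DataFrame:
    """Per-step tallies of flags, corrections and review entries,
    reconciling with the ledger."""
    rows = []
    flags = result.ledger.flags_frame()
    corr = result.ledger.corrections_frame()
    review = result.review.to_frame()

    def major(step_id: str) -> str:
        return step_id.split(".")[0]

    majors = sorted(
        set(flags["step_id"].map(major)) | set(corr["step_id"].map(major)) |
        set(review["step_id"].map(major)),
        key=lambda s: (len(s), s)) if (len(flags) + len(corr) +
                                       len(review)) else []
    for m in majors:
        fsub = flags[flags["step_id"].map(major) == m]
        rows.append({
            "step": m,
            "exclusions": int((fsub["flag"] == "exclusion").sum()),
            "duplicates": int((fsub["flag"] == "duplicate").sum()),
            "deletions": int((fsub["flag"] == "deletion").sum()),
            "links_disregarded": int((fsub["flag"] == "disregard_link").sum()),
            "corrections": int((corr["step_id"].map(major) == m).sum()),
            "review": int((review["step_id"].map(major) == m).sum()),
        })
    return pd.DataFrame(rows, columns=["step", "exclusions", "duplicates",
                                       "deletions", "links_disregarded",
                                       "corrections", "review"])


def cleaned_tables(tables: dict[str, pd.DataFrame],
                   result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Analysis-ready views: corrections applied, flagged records dropped,
    records of excluded persons removed, only accepted links retained.
    Re-running the pipeline on these views is a fixed point."""
    ledger = result.ledger
    excluded = ledger.excluded_persons()
    out: dict[str, pd.DataFrame] = {}
    per = active_perinatal(tables["perinatal"], ledger)
    out["perinatal"] = per.reset_index(drop=True)
    keep_persons = set(per["mum_ppn"].astype(str)) | \
        set(per["baby_ppn"].astype(str))
    if "encounters" in tables:
        enc = active_records(tables["encounters"], ledger)
        enc = enc[~enc["ppn"].astype(str).isin(excluded)]
        out["encounters"] = enc.reset_index(drop=True)
    if "deaths" in tables:
        dea = active_records(tables["deaths"], ledger)
        dea = dea[~dea["ppn"].astype(str).isin(excluded)]
        out["deaths"] = dea.reset_index(drop=True)
    if "congenital" in tables and tables["congenital"] is not None:
        con = active_records(tables["congenital"], ledger)
        con = con[con["baby_ppn"].astype(str).isin(keep_persons)]
        out["congenital"] = con.reset_index(drop=True)
    if result.links is not None:
        keep = result.links[result.links["status"] == "accepted"]
        keep = keep[~keep["mum_ppn"].astype(str).isin(excluded)]
        out["mapping"] = keep.drop(columns=["status"]).reset_index(drop=True)
        if "claims" in tables and tables["claims"] is not None:
            patids = set(keep["patid"].astype(str))
            clm = tables["claims"]
            out["claims"] = clm[clm["patid"].astype(str).isin(patids)] \
                .reset_index(drop=True)
    return out
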