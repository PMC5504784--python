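"""Synthetic two-jurisdiction linked perinatal cohort with labelled error
injection.

The generator emulates the table layout of a cross-jurisdictional linkage:
birth notifications, mother and baby hospital/ED episodes, death
registrations (two streams in jurisdiction A, one in B), congenital-condition
notifications (A only), pharmaceutical claims keyed by a separate PATID
space, and probabilistic PATID-to-mumPPN mapping tables with decoy
sub-threshold matches.  A clean cohort satisfies every consistency rule by
construction: parity increases by one per pregnancy, inter-pregnancy
intervals are positive, dates of birth agree across sources, no service use
follows death, and every woman maps to exactly one above-threshold PATID
(cross-state women map their single PATID to one PPN per state).

:func:`inject_errors` then corrupts a clean cohort with a configurable count
of each error class the cleaning protocol detects, touching only the
targeted rows and recording ground truth (class, targets, the flag and step
expected to catch it) for recovery testing.  Persons touched by one
injection are never reused by another, so every emitted flag is attributable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from datetime import timedelta

import numpy as np
import pandas as pd

from .io import TABLE_COLUMNS, coerce_table

DEFAULT_HYSTERECTOMY_CODES = ["3565300", "3565301", "3565700"]

_ITEM_CODES = ["00020K", "01234A", "02345B", "08521C", "10023D"]

TRUTH_COLUMNS = ["error_class", "scope", "target_ids",
                 "expected_flag", "expected_step_id"]


@dataclass
class CohortConfig:
    """Study-condition parameters for the clean cohort.

    Death rates are set well above population perinatal mortality so that
    the mortality-dependent rules have enough eligible persons to exercise;
    the remaining defaults approximate Australian perinatal statistics
    (plural pregnancy ~1.5%, gestation centred on 39 completed weeks,
    deliveries spread over 2003-2012).
    """

    n_mothers_per_jurisdiction: int = 1000
    pregnancies_per_mother: dict = field(default_factory=lambda: {
        1: 0.45, 2: 0.35, 3: 0.13, 4: 0.05, 5: 0.015, 6: 0.005})
    plural_pregnancy_rate: float = 0.015
    triplet_rate_given_plural: float = 0.03
    gestation_mean: float = 39.0
    gestation_sd: float = 2.0
    gestation_range: tuple = (20, 44)
    birthweight_range: tuple = (400, 5000)
    interval_days_range: tuple = (30, 900)
    mother_extra_encounters_mean: float = 1.2
    baby_extra_encounters_mean: float = 0.8
    mother_death_rate: float = 0.025
    baby_death_rate: float = 0.015
    terminal_admission_rate: float = 0.7
    claims_per_mother_mean: float = 8.0
    congenital_rate: float = 0.05
    decoy_link_rate: float = 0.10
    cross_state_mother_rate: float = 0.01
    thresholds: dict = field(default_factory=lambda: {"A": 29.0, "B": 28.0})
    first_delivery_years: tuple = (2003, 2008)
    mother_birth_years: tuple = (1963, 1987)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mothers_per_jurisdiction < 1:
            raise ValueError("n_mothers_per_jurisdiction must be >= 1")
        total = sum(self.pregnancies_per_mother.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("pregnancies_per_mother must sum to 1")
        for name in ("plural_pregnancy_rate", "mother_death_rate",
                     "baby_death_rate", "decoy_link_rate",
                     "cross_state_mother_rate", "terminal_admission_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if set(self.thresholds) != {"A", "B"}:
            raise ValueError("thresholds must cover jurisdictions A and B only")


@dataclass
class ErrorInjectionPlan:
    """Counts of each error class to inject; every injected instance is
    recorded in the ground-truth table."""

    identical_duplicate: int = 0
    partial_death_duplicate: int = 0
    shared_baby_ppn_across_mothers: int = 0
    baby_ppn_double_entry: int = 0
    implausible_birth_order: int = 0
    negative_interval_false_link: int = 0
    missing_parity: int = 0
    parity_typo: int = 0
    parity_illogical_false_link: int = 0
    dob_typo_in_perinatal: int = 0
    dob_typo_in_encounter: int = 0
    congenital_mismatch: int = 0
    yob_out_of_range: int = 0
    sex_male_with_yob_conflict: int = 0
    birth_after_hysterectomy: int = 0
    dob_after_separation: int = 0
    service_after_death: int = 0
    admission_after_separation: int = 0
    patid_split_across_ppns: int = 0
    patid_merging_two_women: int = 0
    supply_after_death: int = 0
    multi_patid_per_mother_inconsistent: int = 0
    seed: int = 0

    @classmethod
    def uniform(cls, n: int, seed: int = 0) -> "ErrorInjectionPlan":
        kwargs = {f.name: n for f in dc_fields(cls) if f.name != "seed"}
        return cls(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Clean cohort generation

def _ts(year: int, month: int, day: int) -> pd.Timestamp:
    return pd.Timestamp(int(year), int(month), int(day))


class _Counter:
    def __init__(self, prefix: str):
        self.prefix = prefix
        self.n = 0

    def next(self) -> str:
        self.n += 1
        return f"{self.prefix}{self.n:07d}"


def generate_clean_cohort(config: CohortConfig
                          ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate all source tables for a clean cohort.

    Returns ``(tables, truth)`` where ``truth`` is empty: a clean cohort,
    run through the full pipeline, produces no exclusion, duplicate or
    deletion flags.
    """
    rng = np.random.default_rng(config.seed)
    kk = sorted(config.pregnancies_per_mother)
    kp = np.array([config.pregnancies_per_mother[k] for k in kk], dtype=float)
    kp = kp / kp.sum()

    per_rows: list[dict] = []
    enc_rows: list[dict] = []
    death_rows: list[dict] = []
    cong_rows: list[dict] = []
    claim_rows: list[dict] = []
    map_rows: list[dict] = []

    rid = {"per": _Counter("PER"), "enc": _Counter("ENC"),
           "dea": _Counter("DEA"), "con": _Counter("CON"),
           "clm": _Counter("CLM")}
    epoch = _ts(2003, 1, 1)
    data_end = _ts(2013, 6, 30)

    n_cross = int(round(config.cross_state_mother_rate
                        * config.n_mothers_per_jurisdiction))
    women = []
    widx = 0
    for jur in ("A", "B"):
        for i in range(config.n_mothers_per_jurisdiction):
            widx += 1
            cross = jur == "A" and i < n_cross
            women.append({"idx": widx, "home": jur, "cross": cross})

    baby_counter = _Counter("B")

    for w in women:
        jur = w["home"]
        ppn = {jur: f"M{jur}{w['idx']:06d}"}
        if w["cross"]:
            ppn["B"] = f"MB{w['idx']:06d}X"
        w["ppn"] = ppn
        yob = int(rng.integers(config.mother_birth_years[0],
                               config.mother_birth_years[1] + 1))
        mdob = _ts(yob, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        w["mother_dob"] = mdob
        w["postcode"] = f"{int(rng.integers(2000, 7000))}"
        w["country"] = "AU" if rng.random() < 0.8 else "NZ"
        w["patid"] = f"T{w['idx']:06d}"

        k = int(rng.choice(kk, p=kp))
        if w["cross"]:
            k = max(k, 2)
        split = int(rng.integers(1, k)) if w["cross"] else k
        y0 = int(rng.integers(config.first_delivery_years[0],
                              config.first_delivery_years[1] + 1))
        dob = _ts(y0, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        pregnancies = []
        for i in range(k):
            gest = int(np.clip(round(rng.normal(config.gestation_mean,
                                                config.gestation_sd)),
                               *config.gestation_range))
            if i > 0:
                interval = int(rng.integers(*config.interval_days_range))
                conception = prev_dob + timedelta(days=7 + interval)
                dob = conception + timedelta(days=7 * gest - 14)
            if dob > _ts(2012, 12, 31):
                break
            plural = rng.random() < config.plural_pregnancy_rate
            n_babies = 1 if not plural else (
                3 if rng.random() < config.triplet_rate_given_plural else 2)
            p_jur = jur if i < split or not w["cross"] else "B"
            babies = []
            for order in range(1, n_babies + 1):
                bw_mean = 3400 - 160 * (40 - gest) - (400 if n_babies > 1 else 0)
                bw = int(np.clip(round(rng.normal(bw_mean, 350)),
                                 *config.birthweight_range))
                babies.append({
                    "ppn": baby_counter.next(),
                    "bw": bw,
                    "order": order,
                    "apgar": int(rng.choice([8, 9, 10], p=[0.1, 0.5, 0.4])),
                    "sex": "female" if rng.random() < 0.49 else "male",
                })
            pregnancies.append({"dob": dob, "gest": gest, "parity": i,
                                "jur": p_jur, "babies": babies})
            prev_dob = dob
        w["pregnancies"] = pregnancies
        if not pregnancies:
            continue

        # perinatal records + delivery admissions + baby birth admissions
        for preg in pregnancies:
            p_jur = preg["jur"]
            mum = ppn[p_jur]
            for b in preg["babies"]:
                per_rows.append({
                    "record_id": rid["per"].next(), "jurisdiction": p_jur,
                    "mum_ppn": mum, "baby_ppn": b["ppn"],
                    "baby_dob": preg["dob"], "gestational_age": preg["gest"],
                    "birthweight": b["bw"], "parity": preg["parity"],
                    "plurality": len(preg["babies"]),
                    "birth_order": b["order"], "mother_yob": mdob.year,
                    "mother_age": preg["dob"].year - mdob.year,
                    "apgar5": b["apgar"], "discharge_status": "home",
                    "postcode": w["postcode"],
                    "country_of_birth": w["country"],
                    "hospital": f"H{int(rng.integers(1, 31)):02d}",
                })
            sep = preg["dob"] + timedelta(days=int(rng.integers(2, 6)))
            enc_rows.append({
                "record_id": rid["enc"].next(), "jurisdiction": p_jur,
                "ppn": mum, "role": "mother", "source": "hospital",
                "admission_date": preg["dob"] - timedelta(days=1),
                "separation_date": sep, "patient_dob": mdob,
                "patient_yob": mdob.year,
                "patient_age": preg["dob"].year - mdob.year,
                "patient_sex": "female", "month_of_birth": mdob.month,
                "procedure_codes": "9046800", "discharge_status": "home",
                "is_delivery": 1,
            })
            for b in preg["babies"]:
                enc_rows.append({
                    "record_id": rid["enc"].next(), "jurisdiction": p_jur,
                    "ppn": b["ppn"], "role": "baby", "source": "hospital",
                    "admission_date": preg["dob"],
                    "separation_date": preg["dob"] + timedelta(
                        days=int(rng.integers(2, 5))),
                    "patient_dob": preg["dob"], "patient_yob": preg["dob"].year,
                    "patient_age": 0, "patient_sex": b["sex"],
                    "month_of_birth": preg["dob"].month,
                    "procedure_codes": None, "discharge_status": "home",
                    "is_delivery": 0,
                })
                if p_jur == "A" and rng.random() < config.congenital_rate:
                    cong_rows.append({
                        "record_id": rid["con"].next(), "baby_ppn": b["ppn"],
                        "baby_dob": preg["dob"], "birthweight": b["bw"],
                    })

        def _extra_encounters(person_ppn, role, p_jur, dob_floor, mean,
                              dob, mob, yob_, sex):
            n = int(rng.poisson(mean))
            if n == 0:
                return
            lo = max(0, (dob_floor - epoch).days)
            hi = (data_end - epoch).days - 10
            if hi - lo < n * 8:
                return
            offs = rng.choice(np.arange(lo, hi), size=n, replace=False)
            for off in sorted(int(o) for o in offs):
                adm = epoch + timedelta(days=off)
                sep = adm + timedelta(days=int(rng.integers(0, 4)))
                enc_rows.append({
                    "record_id": rid["enc"].next(), "jurisdiction": p_jur,
                    "ppn": person_ppn, "role": role,
                    "source": "hospital" if rng.random() < 0.5 else "ed",
                    "admission_date": adm, "separation_date": sep,
                    "patient_dob": dob, "patient_yob": yob_,
                    "patient_age": adm.year - yob_, "patient_sex": sex,
                    "month_of_birth": mob, "procedure_codes": None,
                    "discharge_status": "home", "is_delivery": 0,
                })

        for p_jur, mum in sorted(ppn.items()):
            _extra_encounters(mum, "mother", p_jur, epoch,
                              config.mother_extra_encounters_mean,
                              mdob, mdob.month, mdob.year, "female")
        for preg in pregnancies:
            for b in preg["babies"]:
                # floor past the birth admission so rows cannot coincide
                _extra_encounters(b["ppn"], "baby", preg["jur"],
                                  preg["dob"] + timedelta(days=6),
                                  config.baby_extra_encounters_mean,
                                  preg["dob"], preg["dob"].month,
                                  preg["dob"].year, b["sex"])

    # deaths — always after every recorded event for the person
    enc_by_ppn: dict[str, list[dict]] = {}
    for r in enc_rows:
        enc_by_ppn.setdefault(r["ppn"], []).append(r)

    def _register_death(person_ppn, jur, last_event, dob, mob, yob_, sex):
        dod = last_event + timedelta(days=int(rng.integers(10, 1000)))
        if rng.random() < config.terminal_admission_rate:
            enc_rows.append({
                "record_id": rid["enc"].next(), "jurisdiction": jur,
                "ppn": person_ppn, "role": "mother" if sex == "NA" else "baby",
                "source": "hospital",
                "admission_date": dod - timedelta(days=3),
                "separation_date": dod, "patient_dob": dob,
                "patient_yob": yob_, "patient_age": dod.year - yob_,
                "patient_sex": "female" if sex == "NA" else sex,
                "month_of_birth": mob, "procedure_codes": None,
                "discharge_status": "deceased", "is_delivery": 0,
            })
            enc_by_ppn.setdefault(person_ppn, [])
        streams = ["registration", "causes_of_death"] if jur == "A" else \
            ["registration"]
        for stream in streams:
            death_rows.append({"record_id": rid["dea"].next(),
                               "jurisdiction": jur, "ppn": person_ppn,
                               "date_of_death": dod, "stream": stream})
        return dod

    for w in women:
        if not w.get("pregnancies"):
            w["death"] = None
            continue
        w["death"] = None
        last = max([p["dob"] for p in w["pregnancies"]] +
                   [r["separation_date"] for p_ppn in w["ppn"].values()
                    for r in enc_by_ppn.get(p_ppn, [])])
        if rng.random() < config.mother_death_rate:
            jur = w["pregnancies"][-1]["jur"]
            w["death"] = _register_death(w["ppn"][jur], jur, last,
                                         w["mother_dob"],
                                         w["mother_dob"].month,
                                         w["mother_dob"].year, "NA")
        for preg in w["pregnancies"]:
            for b in preg["babies"]:
                if rng.random() < config.baby_death_rate:
                    blast = max([preg["dob"]] +
                                [r["separation_date"]
                                 for r in enc_by_ppn.get(b["ppn"], [])])
                    _register_death(b["ppn"], preg["jur"], blast,
                                    preg["dob"], preg["dob"].month,
                                    preg["dob"].year, b["sex"])

    # claims + mapping tables
    for w in women:
        if not w.get("pregnancies"):
            continue
        supply_end = min(_ts(2013, 12, 31),
                         w["death"] if w["death"] is not None else data_end)
        n_claims = int(rng.poisson(config.claims_per_mother_mean))
        span = max(1, (supply_end - epoch).days)
        for _ in range(n_claims):
            claim_rows.append({
                "claim_id": rid["clm"].next(), "patid": w["patid"],
                "date_of_supply": epoch + timedelta(
                    days=int(rng.integers(0, span))),
                "item_code": _ITEM_CODES[int(rng.integers(0, len(_ITEM_CODES)))],
                "month_of_birth": w["mother_dob"].month,
                "year_of_birth": w["mother_dob"].year,
            })
        for jur, mum in sorted(w["ppn"].items()):
            thr = config.thresholds[jur]
            map_rows.append({"patid": w["patid"], "mum_ppn": mum,
                             "jurisdiction": jur,
                             "weight": round(thr + 0.1 + rng.random() * 14, 2)})

    # sub-threshold decoy links exercising the extraction filter
    candidates = [w for w in women if w.get("pregnancies")]
    for i, w in enumerate(candidates):
        if rng.random() >= config.decoy_link_rate:
            continue
        other = candidates[(i + 37) % len(candidates)]
        if other is w:
            continue
        jur = w["home"]
        thr = config.thresholds[jur]
        pair = (other["patid"], w["ppn"][jur])
        if any(m["patid"] == pair[0] and m["mum_ppn"] == pair[1]
               for m in map_rows):
            continue
        map_rows.append({"patid": pair[0], "mum_ppn": pair[1],
                         "jurisdiction": jur,
                         "weight": round(17.0 + rng.random() * (thr - 17.5), 2)})

    tables = {
        kind: pd.DataFrame(rows, columns=TABLE_COLUMNS[kind])
        for kind, rows in [("perinatal", per_rows), ("encounters", enc_rows),
                           ("deaths", death_rows), ("congenital", cong_rows),
                           ("claims", claim_rows), ("mapping", map_rows)]
    }
    tables = {k: coerce_table(v, k) for k, v in tables.items()}
    truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    return tables, truth


# ---------------------------------------------------------------------------
# Error injection

def _link_id(patid: str, mum_ppn: str) -> str:
    return f"{patid}|{mum_ppn}"


def _safe_year_shift(ts: pd.Timestamp, years: int) -> pd.Timestamp:
    day = 28 if (ts.month == 2 and ts.day == 29) else ts.day
    return pd.Timestamp(ts.year + years, ts.month, day)


class _Injector:
    """Applies an :class:`ErrorInjectionPlan` to a clean cohort.

    Each injected instance touches only its targeted rows; persons are
    reserved so no two injections interact, which keeps every pipeline flag
    attributable to exactly one ground-truth row.
    """

    def __init__(self, tables: dict[str, pd.DataFrame],
                 plan: ErrorInjectionPlan,
                 thresholds: dict[str, float] | None = None):
        self.plan = plan
        self.rng = np.random.default_rng(plan.seed + 1_000_003)
        self.thresholds = dict(thresholds or {"A": 29.0, "B": 28.0})
        self.t = {k: v.copy() for k, v in tables.items()}
        self.new: dict[str, list[dict]] = {k: [] for k in self.t}
        self.truth: list[dict] = []
        self.used: set[str] = set()
        self._n_new = 0
        self._profile()

    # -- bookkeeping --------------------------------------------------------
    def _profile(self) -> None:
        per = self.t["perinatal"]
        enc = self.t["encounters"]
        deaths = self.t["deaths"]
        mapping = self.t["mapping"]
        claims = self.t["claims"]

        cross_patids = mapping.groupby("patid")["mum_ppn"].nunique()
        cross_ppns = set(
            mapping[mapping["patid"].isin(
                cross_patids[cross_patids > 1].index) &
                (mapping["weight"] >= mapping["jurisdiction"].map(
                    self.thresholds))]["mum_ppn"].astype(str))

        dead = set(deaths["ppn"].astype(str))
        self.death_date = {str(r.ppn): r.date_of_death
                           for r in deaths.itertuples(index=False)}
        evidence = set(
            enc.loc[enc["discharge_status"].astype(str) == "deceased",
                    "ppn"].astype(str))

        patid_of: dict[str, str] = {}
        for r in mapping.itertuples(index=False):
            thr = self.thresholds[str(r.jurisdiction)]
            if float(r.weight) >= thr:
                patid_of[str(r.mum_ppn)] = str(r.patid)
        n_claims = claims.groupby("patid").size() if not claims.empty else {}

        self.mothers: dict[str, dict] = {}
        for mum, grp in per.groupby(per["mum_ppn"].astype(str), sort=True):
            grp = grp.sort_values(["baby_dob", "birth_order", "record_id"])
            deliveries: list[dict] = []
            for dob, d in grp.groupby("baby_dob", sort=True):
                d = d.sort_values("birth_order")
                deliveries.append({"dob": dob, "idx": list(d.index),
                                   "plural": len(d) > 1})
            menc = enc[(enc["ppn"].astype(str) == mum)]
            self.mothers[mum] = {
                "ppn": mum,
                "jur": str(grp["jurisdiction"].iloc[0]),
                "yob": int(grp["mother_yob"].iloc[0]),
                "deliveries": deliveries, "k": len(deliveries),
                "dead": mum in dead, "cross": mum in cross_ppns,
                "enc_idx": sorted(menc.index, key=lambda i: enc.at[i, "record_id"]),
                "patid": patid_of.get(mum),
                "n_claims": int(n_claims.get(patid_of.get(mum), 0))
                if patid_of.get(mum) else 0,
            }
        self.babies: dict[str, dict] = {}
        for r in per.itertuples():
            b = str(r.baby_ppn)
            benc = enc[enc["ppn"].astype(str) == b]
            self.babies[b] = {
                "ppn": b, "mum": str(r.mum_ppn), "idx": r.Index,
                "dob": r.baby_dob, "plurality": int(r.plurality),
                "dead": b in dead,
                "enc_idx": sorted(benc.index,
                                  key=lambda i: enc.at[i, "record_id"]),
            }
        self.dead_persons = []
        reg = deaths[deaths["stream"] == "registration"]
        for r in reg.sort_values("record_id").itertuples():
            ppn = str(r.ppn)
            self.dead_persons.append({
                "ppn": ppn, "dod": r.date_of_death, "reg_idx": r.Index,
                "reg_id": str(r.record_id), "jur": str(r.jurisdiction),
                "evidence": ppn in evidence,
                "mum": ppn if ppn in self.mothers else self.babies[ppn]["mum"],
            })

    def _reserve(self, *ppns: str) -> None:
        for p in ppns:
            self.used.add(p)
            if p in self.babies:
                self.used.add(self.babies[p]["mum"])

    def _pick_mothers(self, n: int, pred, what: str) -> list[dict]:
        pool = [m for mum, m in sorted(self.mothers.items())
                if not m["cross"] and mum not in self.used and pred(m)]
        order = self.rng.permutation(len(pool))
        chosen = [pool[i] for i in order[:n]]
        if len(chosen) < n:
            raise ValueError(f"not enough eligible mothers for {what}: "
                             f"need {n}, have {len(chosen)}")
        for m in chosen:
            self._reserve(m["ppn"])
        return chosen

    def _pick_dead(self, n: int, pred, what: str) -> list[dict]:
        pool = [d for d in self.dead_persons
                if d["mum"] not in self.used and d["ppn"] not in self.used
                and not self.mothers.get(d["mum"], {}).get("cross", False)
                and pred(d)]
        order = self.rng.permutation(len(pool))
        chosen = [pool[i] for i in order[:n]]
        if len(chosen) < n:
            raise ValueError(f"not enough eligible deaths for {what}: "
                             f"need {n}, have {len(chosen)}")
        for d in chosen:
            self._reserve(d["ppn"], d["mum"])
        return chosen

    def _record(self, error_class: str, scope: str, targets, flag: str,
                step: str) -> None:
        if isinstance(targets, str):
            targets = [targets]
        self.truth.append({
            "error_class": error_class, "scope": scope,
            "target_ids": ";".join(str(t) for t in targets),
            "expected_flag": flag, "expected_step_id": step,
        })

    def _new_id(self, base: str, tag: str) -> str:
        self._n_new += 1
        return f"{base}{tag}{self._n_new}"

    def _copy_row(self, kind: str, idx) -> dict:
        return self.t[kind].loc[idx].to_dict()

    def _singleton_delivery(self, m: dict, position=None):
        cands = [d for d in m["deliveries"] if not d["plural"]]
        if position is not None:
            cands = [d for i, d in enumerate(m["deliveries"])
                     if not d["plural"] and i in position]
        return cands[0] if cands else None

    # -- error classes ------------------------------------------------------
    def identical_duplicate(self, n: int) -> None:
        kinds = ["perinatal", "encounters", "deaths"]
        done = 0
        i = 0
        while done < n:
            kind = kinds[i % len(kinds)]
            i += 1
            if kind == "perinatal":
                ms = self._pick_mothers(1, lambda m: True, "identical_duplicate")
                idx = ms[0]["deliveries"][0]["idx"][0]
            elif kind == "encounters":
                ms = self._pick_mothers(1, lambda m: len(m["enc_idx"]) > 0,
                                        "identical_duplicate")
                idx = ms[0]["enc_idx"][0]
            else:
                try:
                    ds = self._pick_dead(1, lambda d: True, "identical_duplicate")
                except ValueError:
                    continue
                idx = ds[0]["reg_idx"]
                kind = "deaths"
            row = self._copy_row(kind, idx)
            rid_col = "record_id"
            new_id = f"{row[rid_col]}Z{self._n_new}"
            self._n_new += 1
            row[rid_col] = new_id
            self.new[kind].append(row)
            self._record("identical_duplicate", "record", new_id,
                         "duplicate", "S1.1")
            done += 1

    def partial_death_duplicate(self, n: int) -> None:
        for i in range(n):
            if i % 2 == 0:
                d = self._pick_dead(1, lambda d: d["evidence"],
                                    "partial_death_duplicate")[0]
                expect = "duplicate"
            else:
                d = self._pick_dead(1, lambda d: not d["evidence"],
                                    "partial_death_duplicate")[0]
                expect = "review"
            row = self._copy_row("deaths", d["reg_idx"])
            new_id = f"{row['record_id']}P{self._n_new}"
            self._n_new += 1
            row["record_id"] = new_id
            row["date_of_death"] = d["dod"] + timedelta(days=30)
            self.new["deaths"].append(row)
            targets = new_id if expect == "duplicate" else \
                [d["reg_id"], new_id]
            self._record("partial_death_duplicate", "record", targets,
                         expect, "S1.2")

    def shared_baby_ppn_across_mothers(self, n: int) -> None:
        for _ in range(n):
            donor = self._pick_mothers(1, lambda m: True,
                                       "shared_baby_ppn")[0]
            victim = self._pick_mothers(
                1, lambda m: self._singleton_delivery(m) is not None,
                "shared_baby_ppn")[0]
            b1 = str(self.t["perinatal"].at[donor["deliveries"][0]["idx"][0],
                                            "baby_ppn"])
            vidx = self._singleton_delivery(victim)["idx"][0]
            self.t["perinatal"].at[vidx, "baby_ppn"] = b1
            self._record("shared_baby_ppn_across_mothers", "person",
                         [donor["ppn"], victim["ppn"]], "exclusion", "S3.3")

    def baby_ppn_double_entry(self, n: int) -> None:
        for _ in range(n):
            m = self._pick_mothers(
                1, lambda m: self._singleton_delivery(m) is not None,
                "baby_ppn_double_entry")[0]
            idx = self._singleton_delivery(m)["idx"][0]
            row = self._copy_row("perinatal", idx)
            new_id = f"{row['record_id']}Y{self._n_new}"
            self._n_new += 1
            row["record_id"] = new_id
            row["parity"] = pd.NA
            self.new["perinatal"].append(row)
            self._record("baby_ppn_double_entry", "record", new_id,
                         "duplicate", "S3.4")

    def implausible_birth_order(self, n: int) -> None:
        for _ in range(n):
            m = self._pick_mothers(
                1, lambda m: self._singleton_delivery(m) is not None,
                "implausible_birth_order")[0]
            idx = self._singleton_delivery(m)["idx"][0]
            self.t["perinatal"].at[idx, "birth_order"] = 2
            self._record("implausible_birth_order", "record",
                         str(self.t["perinatal"].at[idx, "record_id"]),
                         "review", "S5.1")

    def negative_interval_false_link(self, n: int) -> None:
        for _ in range(n):
            m = self._pick_mothers(1, lambda m: not m["dead"],
                                   "negative_interval")[0]
            last = m["deliveries"][-1]
            row = self._copy_row("perinatal", last["idx"][0])
            row["record_id"] = self._new_id("PERX", "N")
            row["baby_ppn"] = self._new_id("BX", "N")
            row["baby_dob"] = last["dob"] + timedelta(days=30)
            row["gestational_age"] = 38
            row["parity"] = m["k"]
            row["plurality"] = 1
            row["birth_order"] = 1
            row["mother_age"] = row["baby_dob"].year - m["yob"]
            self.new["perinatal"].append(row)
            self._record("negative_interval_false_link", "person",
                         m["ppn"], "exclusion", "S6.4")

    def missing_parity(self, n: int) -> None:
        for _ in range(n):
            def eligible(m):
                if m["k"] >= 3 and self._singleton_delivery(
                        m, range(1, m["k"] - 1)):
                    return True
                return m["k"] == 2 and not m["deliveries"][0]["plural"]
            m = self._pick_mothers(1, eligible, "missing_parity")[0]
            if m["k"] >= 3:
                d = self._singleton_delivery(m, range(1, m["k"] - 1))
                step = "S7.5.3"
            else:
                d = m["deliveries"][0]
                step = "S7.5.1"
            idx = d["idx"][0]
            self.t["perinatal"].at[idx, "parity"] = pd.NA
            self._record("missing_parity", "record",
                         str(self.t["perinatal"].at[idx, "record_id"]),
                         "correction", step)

    def parity_typo(self, n: int) -> None:
        for _ in range(n):
            m = self._pick_mothers(1, lambda m: m["k"] >= 2, "parity_typo")[0]
            last = m["deliveries"][-1]
            for idx in last["idx"]:
                self.t["perinatal"].at[idx, "parity"] = m["k"] - 1 + 10
            self._record("parity_typo", "record",
                         str(self.t["perinatal"].at[last["idx"][0],
                                                    "record_id"]),
                         "correction", "S8.2.4")

    def parity_illogical_false_link(self, n: int) -> None:
        for _ in range(n):
            m = self._pick_mothers(1, lambda m: m["k"] >= 4,
                                   "parity_illogical")[0]
            for d in m["deliveries"]:
                for idx in d["idx"]:
                    self.t["perinatal"].at[idx, "parity"] = 0
            self._record("parity_illogical_false_link", "person",
                         m["ppn"], "exclusion", "S8.3.1")

    def dob_typo_in_perinatal(self, n: int) -> None:
        for _ in range(n):
            m = self._pick_mothers(
                1, lambda m: self._singleton_delivery(m) is not None,
                "dob_typo_in_perinatal")[0]
            d = self._singleton_delivery(m)
            idx = d["idx"][0]
            self.t["perinatal"].at[idx, "baby_dob"] = \
                d["dob"] + timedelta(days=10)
            self._record("dob_typo_in_perinatal", "record",
                         str(self.t["perinatal"].at[idx, "record_id"]),
                         "correction", "S9.3")

    def dob_typo_in_encounter(self, n: int) -> None:
        enc = self.t["encounters"]
        for i in range(n):
            def eligible(m):
                for dref in m["deliveries"]:
                    for idx in dref["idx"]:
                        b = str(self.t["perinatal"].at[idx, "baby_ppn"])
                        if len(self.babies[b]["enc_idx"]) >= 2:
                            return True
                return False
            m = self._pick_mothers(1, eligible, "dob_typo_in_encounter")[0]
            baby = next(
                self.babies[str(self.t["perinatal"].at[idx, "baby_ppn"])]
                for dref in m["deliveries"] for idx in dref["idx"]
                if len(self.babies[
                    str(self.t["perinatal"].at[idx, "baby_ppn"])]["enc_idx"]) >= 2)
            eidx = baby["enc_idx"][-1]
            d = baby["dob"]
            if i % 2 == 0:
                new_dob = _safe_year_shift(d, -1)
                expect = "correction"
            else:
                new_dob = None
                for off in range(150, 260):
                    cand = d + timedelta(days=off)
                    if not ((cand.month == d.month and cand.year == d.year) or
                            (cand.month == d.month and cand.day == d.day) or
                            (cand.day == d.day and cand.year == d.year)):
                        new_dob = cand
                        break
                expect = "deletion"
            enc.at[eidx, "patient_dob"] = new_dob
            enc.at[eidx, "patient_yob"] = new_dob.year
            self._record("dob_typo_in_encounter", "record",
                         str(enc.at[eidx, "record_id"]), expect, "S9.4")

    def congenital_mismatch(self, n: int) -> None:
        for i in range(n):
            if i % 2 == 0:
                m = self._pick_mothers(
                    1, lambda m: m["jur"] == "A" and m["k"] >= 2,
                    "congenital_mismatch")[0]
                d0, d1 = m["deliveries"][0], m["deliveries"][1]
                idx = d0["idx"][0]
                row = {
                    "record_id": self._new_id("CONX", "C"),
                    "baby_ppn": str(self.t["perinatal"].at[idx, "baby_ppn"]),
                    "baby_dob": d1["dob"],
                    "birthweight":
                        int(self.t["perinatal"].at[idx, "birthweight"]) + 500,
                }
                self.new["congenital"].append(row)
                self._record("congenital_mismatch", "person", m["ppn"],
                             "exclusion", "S10.3")
            else:
                m = self._pick_mothers(1, lambda m: m["jur"] == "A",
                                       "congenital_mismatch")[0]
                idx = m["deliveries"][0]["idx"][0]
                row = {
                    "record_id": self._new_id("CONX", "C"),
                    "baby_ppn": str(self.t["perinatal"].at[idx, "baby_ppn"]),
                    "baby_dob": m["deliveries"][0]["dob"] + timedelta(days=17),
                    "birthweight":
                        int(self.t["perinatal"].at[idx, "birthweight"]) + 500,
                }
                self.new["congenital"].append(row)
                self._record("congenital_mismatch", "record",
                             row["record_id"], "review", "S10.3")

    def yob_out_of_range(self, n: int) -> None:
        enc = self.t["encounters"]
        for _ in range(n):
            m = self._pick_mothers(
                1, lambda m: not m["dead"] and len(m["enc_idx"]) >= 2,
                "yob_out_of_range")[0]
            for eidx in m["enc_idx"][:2]:
                old = enc.at[eidx, "patient_dob"]
                day = 28 if (old.month == 2 and old.day == 29) else old.day
                enc.at[eidx, "patient_dob"] = pd.Timestamp(1930, old.month, day)
                enc.at[eidx, "patient_yob"] = 1930
            self._record("yob_out_of_range", "person", m["ppn"],
                         "exclusion", "S11.4")

    def sex_male_with_yob_conflict(self, n: int) -> None:
        enc = self.t["encounters"]
        for _ in range(n):
            m = self._pick_mothers(1, lambda m: len(m["enc_idx"]) >= 2,
                                   "sex_male_with_yob_conflict")[0]
            e1, e2 = m["enc_idx"][:2]
            enc.at[e1, "patient_sex"] = "male"
            enc.at[e2, "patient_sex"] = "male"
            mob = int(enc.at[e2, "month_of_birth"])
            enc.at[e2, "month_of_birth"] = mob % 12 + 1
            self._record("sex_male_with_yob_conflict", "person", m["ppn"],
                         "exclusion", "S12.2")

    def birth_after_hysterectomy(self, n: int) -> None:
        enc = self.t["encounters"]
        for _ in range(n):
            m = self._pick_mothers(1, lambda m: len(m["enc_idx"]) >= 1,
                                   "birth_after_hysterectomy")[0]
            ref = self._copy_row("encounters", m["enc_idx"][0])
            sep = m["deliveries"][-1]["dob"] - timedelta(days=200)
            ref.update({
                "record_id": self._new_id("ENCX", "H"),
                "role": "mother", "source": "hospital",
                "admission_date": sep - timedelta(days=3),
                "separation_date": sep,
                "procedure_codes": DEFAULT_HYSTERECTOMY_CODES[0],
                "discharge_status": "home", "is_delivery": 0,
                "patient_sex": "female",
            })
            ref["patient_age"] = sep.year - int(ref["patient_yob"])
            self.new["encounters"].append(ref)
            self._record("birth_after_hysterectomy", "person", m["ppn"],
                         "exclusion", "S13.3")

    def dob_after_separation(self, n: int) -> None:
        enc = self.t["encounters"]
        for i in range(n):
            def eligible(m):
                return any(
                    len(self.babies[str(self.t["perinatal"].at[idx,
                                                               "baby_ppn"])]
                        ["enc_idx"]) >= 2
                    for dref in m["deliveries"] for idx in dref["idx"])
            m = self._pick_mothers(1, eligible, "dob_after_separation")[0]
            baby = next(
                self.babies[str(self.t["perinatal"].at[idx, "baby_ppn"])]
                for dref in m["deliveries"] for idx in dref["idx"]
                if len(self.babies[
                    str(self.t["perinatal"].at[idx, "baby_ppn"])]["enc_idx"]) >= 2)
            eidx = baby["enc_idx"][-1]
            d = baby["dob"]
            enc.at[eidx, "admission_date"] = d - timedelta(days=20)
            enc.at[eidx, "separation_date"] = d - timedelta(days=15)
            if i % 2 == 0:
                self._record("dob_after_separation", "record",
                             str(enc.at[eidx, "record_id"]), "deletion",
                             "S14.3")
            else:
                enc.at[eidx, "patient_dob"] = _safe_year_shift(d, -1)
                enc.at[eidx, "patient_yob"] = d.year - 1
                self._record("dob_after_separation", "person", baby["ppn"],
                             "exclusion", "S14.3")

    def service_after_death(self, n: int) -> None:
        for _ in range(n):
            d = self._pick_dead(1, lambda d: True, "service_after_death")[0]
            ppn = d["ppn"]
            src = self.mothers[ppn] if ppn in self.mothers else self.babies[ppn]
            ref = self._copy_row("encounters", src["enc_idx"][0])
            ref.update({
                "record_id": self._new_id("ENCX", "S"),
                "source": "hospital",
                "admission_date": d["dod"] + timedelta(days=5),
                "separation_date": d["dod"] + timedelta(days=10),
                "discharge_status": "home", "is_delivery": 0,
                "procedure_codes": None,
            })
            ref["patient_age"] = ref["admission_date"].year - \
                int(ref["patient_yob"])
            self.new["encounters"].append(ref)
            self._record("service_after_death", "person", ppn,
                         "exclusion", "S15.4")

    def admission_after_separation(self, n: int) -> None:
        enc = self.t["encounters"]
        for _ in range(n):
            def eligible(m):
                return any(enc.at[i, "is_delivery"] == 0 and
                           enc.at[i, "admission_date"] <
                           enc.at[i, "separation_date"]
                           for i in m["enc_idx"])
            m = self._pick_mothers(1, eligible, "admission_after_separation")[0]
            eidx = next(i for i in m["enc_idx"]
                        if enc.at[i, "is_delivery"] == 0 and
                        enc.at[i, "admission_date"] < enc.at[i, "separation_date"])
            adm, sep = enc.at[eidx, "admission_date"], \
                enc.at[eidx, "separation_date"]
            enc.at[eidx, "admission_date"] = sep
            enc.at[eidx, "separation_date"] = adm
            self._record("admission_after_separation", "record",
                         str(enc.at[eidx, "record_id"]), "deletion", "S16.1")

    def patid_split_across_ppns(self, n: int) -> None:
        per = self.t["perinatal"]
        enc = self.t["encounters"]
        for _ in range(n):
            m = self._pick_mothers(
                1, lambda m: not m["dead"] and m["k"] >= 2 and m["patid"],
                "patid_split_across_ppns")[0]
            new_ppn = m["ppn"] + "S"
            split = m["k"] // 2
            split_dob = m["deliveries"][split]["dob"]
            for d in m["deliveries"][split:]:
                for idx in d["idx"]:
                    per.at[idx, "mum_ppn"] = new_ppn
            for eidx in m["enc_idx"]:
                if enc.at[eidx, "admission_date"] >= \
                        split_dob - timedelta(days=1):
                    enc.at[eidx, "ppn"] = new_ppn
            self.new["mapping"].append({
                "patid": m["patid"], "mum_ppn": new_ppn,
                "jurisdiction": m["jur"],
                "weight": self.thresholds[m["jur"]] + 2.0})
            self._record("patid_split_across_ppns", "person",
                         [m["ppn"], new_ppn], "cluster_accept", "S19")

    def patid_merging_two_women(self, n: int) -> None:
        for _ in range(n):
            ma = self._pick_mothers(
                1, lambda m: m["jur"] == "A" and not m["dead"] and m["patid"],
                "patid_merging_two_women")[0]
            mb = self._pick_mothers(
                1, lambda m: (m["jur"] == "B" and not m["dead"] and
                              m["patid"] and m["yob"] != ma["yob"]),
                "patid_merging_two_women")[0]
            self.new["mapping"].append({
                "patid": ma["patid"], "mum_ppn": mb["ppn"],
                "jurisdiction": "B", "weight": self.thresholds["B"]})
            self._record("patid_merging_two_women", "record",
                         _link_id(ma["patid"], mb["ppn"]),
                         "disregard_link", "S20.12")

    def supply_after_death(self, n: int) -> None:
        for _ in range(n):
            d = self._pick_dead(
                1, lambda d: d["ppn"] in self.mothers and
                self.mothers[d["ppn"]]["patid"], "supply_after_death")[0]
            m = self.mothers[d["ppn"]]
            self.new["claims"].append({
                "claim_id": self._new_id("CLMX", "S"),
                "patid": m["patid"],
                "date_of_supply": d["dod"] + timedelta(days=30),
                "item_code": _ITEM_CODES[0],
                "month_of_birth": pd.NA, "year_of_birth": pd.NA,
            })
            self._record("supply_after_death", "record",
                         _link_id(m["patid"], m["ppn"]),
                         "disregard_link", "S18.2")

    def multi_patid_per_mother_inconsistent(self, n: int) -> None:
        for _ in range(n):
            m = self._pick_mothers(
                1, lambda m: not m["dead"] and m["patid"] and
                m["n_claims"] >= 1, "multi_patid_inconsistent")[0]
            new_patid = self._new_id("TX", "M")
            self.new["mapping"].append({
                "patid": new_patid, "mum_ppn": m["ppn"],
                "jurisdiction": m["jur"],
                "weight": self.thresholds[m["jur"]] + 1.5})
            for j in range(3):
                self.new["claims"].append({
                    "claim_id": self._new_id("CLMX", "M"),
                    "patid": new_patid,
                    "date_of_supply": _ts(2008, 1, 15) + timedelta(days=30 * j),
                    "item_code": _ITEM_CODES[1],
                    "month_of_birth": pd.NA,
                    "year_of_birth": m["yob"] + 1,
                })
            self._record("multi_patid_per_mother_inconsistent", "person",
                         m["ppn"], "exclusion", "S22.2")

    # -- driver -------------------------------------------------------------
    #: classes competing for the scarcest persons (deceased mothers) run
    #: first so that large plans remain feasible
    _PRIORITY = ["supply_after_death", "service_after_death",
                 "partial_death_duplicate"]

    def run(self) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
        names = [f.name for f in dc_fields(self.plan) if f.name != "seed"]
        ordered = self._PRIORITY + [n for n in names
                                    if n not in self._PRIORITY]
        for name in ordered:
            count = getattr(self.plan, name)
            if count:
                getattr(self, name)(int(count))
        out = {}
        for kind, df in self.t.items():
            if self.new[kind]:
                extra = coerce_table(
                    pd.DataFrame(self.new[kind], columns=TABLE_COLUMNS[kind]),
                    kind)
                df = pd.concat([df, extra], ignore_index=True)
            out[kind] = coerce_table(df, kind)
        truth = pd.DataFrame(self.truth, columns=TRUTH_COLUMNS)
        return out, truth


def inject_errors(tables: dict[str, pd.DataFrame], plan: ErrorInjectionPlan,
                  thresholds: dict[str, float] | None = None
                  ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Corrupt a clean cohort according to *plan*.

    Returns ``(tables, truth)``; the truth table maps one-to-one to
    injections with the flag and step expected to catch each.  Raises
    ``ValueError`` when the plan is infeasible for the cohort (for example
    more hysterectomy errors than eligible mothers).
    """
    return _Injector(tables, plan, thresholds).run()
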