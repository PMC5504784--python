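# Methods

## Model and assumptions

`linkclean` treats linked perinatal data as a family of tables keyed by
opaque person numbers: one birth-notification record per baby (plural
pregnancies produce one record per baby sharing the maternal fields),
hospital/ED episodes per person, death registrations (split into a
registration stream and a causes-of-death stream where a jurisdiction
delivers both), congenital-condition notifications, and pharmaceutical
claims keyed by a separate PATID space related to mother PPNs only through
probabilistic mapping tables with match weights.

The core assumption — the reason content-based checking works at all — is
that a handful of perinatal items are recorded with high accuracy: baby
date of birth, parity (previous pregnancies of ≥ 20 weeks), plurality,
birth order, gestational age and birthweight.  A woman's own record set is
therefore internally constrained: parity must increase strictly across her
deliveries; the conception of one child (DOB − 7·weeks + 14 days) cannot
precede the delivery of the previous child; her year of birth and sex
should agree across sources.  Violations that are biologically or
chronologically impossible mark false positive links (person-level
exclusions); violations that are plausibly clerical (duplicates, typos,
transposed dates) are flagged at record level or corrected.

Two policies hold throughout:

* **Flag, never delete or overwrite.**  All outcomes are entries in an
  append-only ledger (`FlagLedger`): person-level `exclusion`, record-level
  `duplicate`/`deletion`, link-level `disregard_link`, `review`, and field
  corrections.  Views are derived; source frames are never mutated, and a
  byte-comparison of input files before and after a run is part of the test
  suite.
* **Exclusion propagates through families.**  A linkage error detected for
  a child cannot be repaired by dropping the child alone — analyses of
  prior-pregnancy outcomes would silently break — so an excluded child
  excludes the mother, and an excluded mother marks all her children as an
  excluded family.  Propagated entries inherit the step id of the trigger
  with reason code `family`.

Steps execute in protocol order with apply-before-next semantics; each step
sees views filtered by all prior flags and corrections.  Declared
dependencies (e.g. DOB-after-discharge consumes only post-reconciliation
DOBs) are enforced at configuration time.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| acceptance thresholds | 29.0 (A), 28.0 (B) | minimum match weight to accept a claims link; inclusive |
| release floor | 17.0 | weakest link released at all; 17 ≤ w < threshold forms the sensitivity pool |
| baby YOB validity | 1920–2014 | patient years of birth outside this are dropped before DOB pooling |
| mother YOB validity | 1900–2014 | likewise for mother-record pooling |
| 20-week bound | 140 days | DOB-gap boundary for age correction vs deletion vs exclusion |
| 40-week bound | 280 days | inter-pregnancy interval condition for parity imputation; strict `<` |
| death allowance | 3 days | administrative delay tolerated between death and a recorded service date |
| hysterectomy codes | 3-code ACHI-style list | configurable, one code per line; empty list skips the check |

Boundary decisions are literal readings of the rules and are strict on both
sides: an interval of exactly 0 days is not negative; a discharge exactly
3 days after death is tolerated; a DOB gap of exactly 140 days is neither
"less than" nor "more than" 20 weeks and resolves to record deletion at the
DOB-reconciliation step, not exclusion at the discharge-ordering step.

## Adjudication rules replacing on-screen review

Manual review in the original workflow is replaced by conservative,
auditable rules; anything the rules decline to decide lands in an exported
review queue rather than being decided silently.

* **Repeated baby records under one mother** — agreement on all
  non-missing shared auxiliary fields (baby DOB, plurality, birth order,
  birthweight, gestational age, Apgar score, discharge status, mother's
  age, postcode, country of birth, hospital) with at least three
  comparable fields ⇒ duplicate (lowest record id kept); disagreement ⇒
  exclusion; fewer than three comparable fields ⇒ review.
* **Partial death duplicates** — equal dates keep one record; differing
  dates are decided by a hospital separation with deceased discharge
  status; otherwise review.  The registration and causes-of-death streams
  are separate sources: a person legitimately appears once in each, so
  partial-duplicate detection groups per (person, stream).
* **Parity typo repair** — a single record's parity may be replaced by `v`
  when `v` differs from the recorded value in exactly one digit, or the
  recorded value is ≥ 10 amid single-digit neighbours, *and* the repaired
  sequence is strictly increasing with expected = count.  Among competing
  candidates a lone two-digit outlier is preferred (the characteristic
  stray-digit error, e.g. 0-1-2-13 → 0-1-2-3); remaining ambiguity means no
  change.  The repair search triggers when expected − count ≥ 4 or
  expected ≥ 10.
* **Multi-match PATIDs** — the linkage-unit advice of the original
  workflow is emulated by pre-screening each multi-match component with
  the same consistency battery used for cluster validation (intervals,
  parity, YOB, service-after-death); consistent components become clusters,
  inconsistent ones keep the maximum-weight link (ties: more perinatal
  records, then PPN order) with a review entry.
* **"Admission indicates birth delivery"** — a boolean `is_delivery`
  column on hospital records (synthetic data sets it; real extracts can
  derive it from diagnosis/procedure codes upstream).
* **Cluster/cross YOB check** — a two-member group of two different women
  with distinct in-range years of birth cannot trip the literal
  within-state rule (≥ 2 out-of-range or > 3 distinct), so the pooled
  battery additionally fails when the pooled *perinatal* mother years of
  birth are not all equal; perinatal YOB is the validated item.

## The synthetic cohort

The generator emulates structure, not demography: person numbers, dates,
weights and clinical items are drawn from simple parametric models
(gestation ≈ round-normal(39, 2) clipped to 20–44 weeks; birthweight
gestation-dependent, clipped to 400–5000 g; 1–6 pregnancies per mother with
a realistic categorical split; 1.5 % plural pregnancies; inter-pregnancy
intervals of 30–900 days; deliveries spread over 2003–2012).  Cross-state
women (default 1 %) exist as two PPNs, one per jurisdiction, splitting one
parity sequence; every woman maps to exactly one above-threshold PATID,
plus sub-threshold decoy links at a 10 % rate to exercise the extraction
filter.

Death rates (2.5 % of mothers, 1.5 % of babies) are deliberately far above
real perinatal mortality: the mortality-dependent rules (partial death
duplicates, service after death, supply after death) need enough deceased
persons to be exercised with non-trivial injection counts at the default
cohort size of 1,000 mothers per jurisdiction.  This is a test-harness
choice, documented here so nobody mistakes the synthetic rates for
epidemiology.

A clean draw satisfies every rule by construction, so the pipeline's output
on it measures the false-positive behaviour of the checks directly (the
test suite asserts zero flags over 20 seeds).  The injector corrupts only
targeted rows, reserves each touched family for a single injection, and
emits a ground-truth table (class, targets, expected flag, expected step);
`linkclean.evaluate` scores recovery and attributes every emitted flag to
an injection, directly or through family propagation.  What passing these
tests does *not* show: robustness to correlated real-world messiness
(shared typo patterns across sources, systematic coding changes over time,
missingness that is informative rather than random) — the generator draws
errors independently.

## Numerical and determinism choices

Dates are day-granular calendar dates; all differences are exact day
counts; no timezone semantics.  Missing values are empty CSV fields and
nullable integers in memory — parity 0 is meaningful and never conflated
with missing.  Every tie-break is deterministic (lowest record id kept,
lexicographic person order, fixed cluster/cross id numbering from sorted
members), so identical inputs give byte-identical ledgers, reports and
resolution maps; the only floating-point values are match weights, which
are compared, never transformed.  The generator and the injector use
separate seeded random streams, so the clean substrate is reproducible
under varying injection plans.

Problem sizes in the shipped tests and the acceptance script (cohorts of
1,000 mothers per jurisdiction, 10–25 injections per class, 200
random-graph trials, a 10,000-case date grid) were chosen as the smallest
sizes at which every rule class is exercised with comfortable eligibility
margins at any seed.

## Known limitations

* The protocol detects only errors that surface as content inconsistency;
  a false positive link between two demographically similar women with
  compatible obstetric histories is invisible, and detection power rises
  with the number of records per person.
* Step-9 DOB reconciliation accepts an alternative date only when exactly
  one candidate survives the safeguards; multiple surviving candidates go
  to review rather than picking a winner.
* ICD/ACHI semantics are out of scope: the hysterectomy code list is
  configuration, and delivery admissions are identified by a marker column.
* Re-linkage is out of scope; match weights are inputs.  The pipeline
  rejects configurations with more than the two supported jurisdictions.
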