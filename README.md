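# linkclean

Consistency checking and cleaning for probabilistically linked perinatal
administrative data.

## The problem

Large perinatal studies link birth notifications to hospital separations,
emergency-department attendances, death registrations, congenital-condition
notifications and pharmaceutical claims.  When no shared person identifier
exists, linkage is probabilistic and imperfect: records of different people
can be fused under one person number (false positive links) and one person's
records can be split across numbers (missed links).  Linkage units see only
names and addresses; researchers see only content.  `linkclean` implements a
22-step protocol that exploits the *content* — parity sequences, gestational
ages, dates of birth, admission and death dates, match weights — to find
those errors, without ever touching the original data: every decision is a
flag or a correction in an append-only ledger, and analysis views are derived
from ledger plus source tables.

The checks fall into four groups:

1. **Uniqueness (steps 1–3)** — identical and partial duplicates within each
   source; completeness of the death registration stream; a baby person
   number appearing under two different mothers (biologically impossible —
   both families are excluded).
2. **Perinatal consistency (steps 4–8)** — birthweight × gestation
   tabulation; birth order vs plurality; the inter-pregnancy interval

       conception = DOB − 7·(gestational weeks) + 14 days
       interval   = conception(next) − delivery(prior) − 7 days

   (a negative interval means a child was conceived before the previous one
   was delivered: a false positive link); imputation of missing parity from
   neighbouring records; and the parity-span check, comparing the *expected*
   number of pregnancies (`max parity − min parity + 1`) with the number of
   delivery records.  An illogical parity sequence with expected = 1 and
   ≥ 4 records, or expected ≥ 2 and ≥ 2 surplus records, excludes the woman.
3. **Cross-source coherence (steps 9–16)** — reconciling the baby's date of
   birth against the patient DOB on other records using maternal delivery
   admission windows; congenital-notification agreement; mother's year of
   birth and sex across sources; births after total hysterectomy; service
   use after death (3-day administrative allowance); admissions after
   discharge.
4. **Cross-jurisdiction identifier resolution (steps 17–22)** — extracting
   claim links at the recommended match-weight thresholds (≥ 29 in
   jurisdiction A, ≥ 28 in B), resolving one-PATID-to-many-mumPPN clusters
   and cross-state women on connected components of the link graph, and
   collapsing identifiers into `finalPPNmum` with precedence
   CrossID > ClusterID > mumPPN.

Because real linked data are confidential, the package ships a synthetic
cohort generator (`linkclean.synth`) that emulates the full
mother→pregnancy→baby hierarchy across two jurisdictions, plus a labelled
error injector covering all 22 error classes the protocol detects, with
ground truth for recovery testing.

## Worked example

```python
from linkclean import (CohortConfig, ErrorInjectionPlan,
                       generate_clean_cohort, inject_errors,
                       run_pipeline, summarize)

tables, _ = generate_clean_cohort(CohortConfig(n_mothers_per_jurisdiction=200,
                                               seed=42))
plan = ErrorInjectionPlan(negative_interval_false_link=3, parity_typo=2,
                          admission_after_separation=2, seed=42)
bad, truth = inject_errors(tables, plan)
result = run_pipeline(bad)
print(summarize(result).to_string(index=False))
```

prints

```
step  exclusions  duplicates  deletions  links_disregarded  corrections  review
  S6          10           0          0                  0            0       0
  S8           0           0          0                  0            2       0
 S16           0           0          2                  0            0       0
 S22           0           0          0                  3            0       0
```

Reading the rows: the three women injected with overlapping pregnancies are
excluded at step 6 (10 exclusion entries — each excluded mother's children
are flagged with her, so families leave the cohort together); the two
parity typos are corrected (not flagged) at step 8; the two swapped
admission/discharge dates are record deletions at step 16; and step 22
bookkeeping removes the claim links of the excluded women.  On the clean
cohort the same pipeline emits nothing at all.

The same workflow is available from a shell:

```
clean synth --config cohort.yaml --plan errors.yaml --out data/ --seed 42
clean run   --in data/ --out results/ --export-cleaned
clean report --ledger results/flags.csv
```

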