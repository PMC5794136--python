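# pregepi

Infer pregnancy episodes — outcome class, outcome date, start date and
start-estimation method — from OMOP-style observational event tables
(person, observation_period, condition/procedure/observation/drug CSVs).

The algorithm runs in two steps per person:

1. **Outcome classification.** Outcome-category records are assessed in a
   fixed hierarchy (live birth → stillbirth → ectopic → abortion →
   delivery-only). Candidates must clear a configurable minimum-spacing
   table against already-accepted outcomes; stillbirth/ectopic/abortion/
   delivery candidates are discarded when an antenatal-visit or
   pregnancy-confirmation record follows within 42 days; ectopic records
   additionally require treatment (methotrexate/surgery) or an associated
   concept within 14 days, with the outcome date reassigned to the last
   treatment date; abortion dates are reassigned to the last abortion
   record within 14 days; accepted delivery-only records become live
   births.
2. **Start estimation.** The highest-ranked eligible start marker wins and
   its offset is subtracted from the marker date (LMP −0, gestational-age
   record −value, conception-dating fertility procedure −13, nuchal
   ultrasound −89, alpha-fetoprotein test −123, amenorrhea −55, urine
   pregnancy test −55). Eligibility requires the implied term to sit
   strictly inside the outcome's min/max term window (161–301 days for
   live births) and the marker to postdate the prior outcome plus its
   retry period. Without an eligible marker, an outcome- and term-specific
   average gestation (280/245 live birth full/preterm, 196 stillbirth, 56
   ectopic, 70 abortion) is subtracted from the outcome date, clamped
   forward to the prior outcome's retry horizon.

Episodes are then filtered: female, age 12–55 at start, one observation
period spanning the episode, and at least two categorized records inside
it. A disproportionality screen (`ectopic_disproportionality`) curates
concepts over-represented (prevalence ratio > 5) in 60-day post-ectopic
windows versus an eligible reference female population.

A synthetic-cohort generator (`pregepi.simulate`) plants pregnancies with
known conception anchors, emits markers on their gestational schedule,
and can inject claims noise (repeat billings, rule-out abortion codes,
historical outcome codes), so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic cohort with ground truth
pregepi simulate --seed 42 --n-persons 500 --out-dir cohort/

# run the algorithm
pregepi infer --cohort-dir cohort/ --concepts cohort/concept_sets.csv \
    --out pregnancy_episodes.csv --report inclusion_report.json

# characterization tables (proportions, methods, duration histograms)
pregepi characterize --episodes pregnancy_episodes.csv --out-dir tables/

# fertility-procedure start agreement + marker proximity
pregepi sensitivity --episodes pregnancy_episodes.csv --cohort-dir cohort/ \
    --concepts cohort/concept_sets.csv --anchor nuchal_ultrasound --out sensitivity.csv

# reviewer profiles, 50 per outcome
pregepi profiles --episodes pregnancy_episodes.csv --cohort-dir cohort/ \
    --concepts cohort/concept_sets.csv --out-dir profiles/ --per-outcome 50 --seed 0
```

All window tables (spacing, term windows, retry periods, offsets,
gestational estimates) live in `AlgorithmConfig` and can be overridden
with `--config config.yaml`; `AlgorithmConfig().to_yaml(path)` writes the
shipped defaults as a starting point. Spacing-table values, retry
periods, non-live-birth term windows and the preterm estimate are
clearly-labelled configuration defaults, not published constants.

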