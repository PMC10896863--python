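# artgaps

Claims-based measurement of antiretroviral therapy (ART) adherence,
treatment gaps, and discontinuation, with a seeded synthetic Medicare-like
claims generator for development and validation.

## The problem

People with HIV take a three-drug ART regimen indefinitely; adherence to
the regimen's "anchor" agent — the third drug, from the protease-inhibitor
(PI), non-nucleoside reverse-transcriptase-inhibitor (NNRTI), or
integrase-strand-transfer-inhibitor (INSTI) class — is the standard
claims-based proxy for regimen adherence.  Administrative prescription
claims record each fill's date and days' supply, from which one can
measure, over a fixed follow-up window after a new anchor initiation:

* **PDC** (proportion of days covered):
  `PDC = (days covered by any anchor supply) / (eligible days)`,
  where eligible days exclude days spent in a hospital, skilled nursing
  facility, or hospice (medication is dispensed by the facility on those
  days).  Adherence is classed optimal (PDC ≥ 0.95), intermediate
  (0.70 ≤ PDC < 0.95), or low (PDC < 0.70), with additional flags at
  0.70/0.80/0.90/0.95.
* **Treatment gaps**: maximal runs of follow-up days with no anchor supply,
  binned by duration (<7, 7–13, 14–29, 30–89, 90–119, 120–149, 150–179,
  ≥180 days).
* **Discontinuation**: a fully observed continuous gap of ≥ 90 days;
  time to discontinuation is the number of days from the index date to the
  first day of that gap.

Correct day-level coverage requires two adjustments the package implements
as its computational core: **carry-over** (a refill obtained before the
previous same-drug supply runs out starts the day after that supply ends —
a 30-day fill on day 1 refilled on day 28 starts on day 31) and
**facility-stay stockpiling** (supply overlapping a facility stay is
conserved and consumed after discharge).

Because the source data this methodology targets (100% Medicare Part
A/B/D research files) are access-restricted, the package ships a
first-class synthetic claims generator whose cycle-based refill model
(per-cycle stopping hazard, agent switching, early/late refills,
hospitalizations, deaths, covariate-linked effects) makes every downstream
stage testable and lets association models recover planted effect sizes.

Intended users: pharmacoepidemiologists and health-services researchers
building adherence/persistence analyses from prescription claims.

## Pipeline

```
simulate -> select-cohort -> measure -> model -> report
```

* `artgaps.synthetic_claims` — seeded generator of the five claims tables
  (enrollment/beneficiary summary, prescription events, facility stays,
  diagnosis claims, drug catalog) plus a ground-truth table.
* `artgaps.cohort` — new-user index events (first in-window anchor fill
  with a 365-day same-drug washout) and the selection criteria: continuous
  Part A/B/D enrollment 12 months pre/post index, a pre-index HIV
  diagnosis (ICD-9-CM 042, V08, 079.53; ICD-10-CM B20, B97.35,
  O98.711–713, O98.719, O98.72, O98.73, Z21), then exclusion of deaths in
  follow-up, missing key covariates, and multi-anchor index dates — with a
  per-criterion attrition table.
* `artgaps.exposure` — day-level classification of follow-up days 1..365
  as covered / facility / gap, with carry-over and stockpiling.
* `artgaps.outcomes` — PDC, categories, gap runs and bins,
  discontinuation, time to discontinuation; descriptive summaries overall
  and by anchor class.
* `artgaps.models` — multinomial logit on the adherence category
  (optimal as reference), binary logit on discontinuation, and Cox
  regression on time to discontinuation (Efron ties, administrative
  censoring at day 365), over the study covariate list with its published
  reference levels.

## Worked example

```python
from artgaps import AnalysisConfig, SimulationParams, generate_bundle
from artgaps.cohort import identify_index_events, apply_selection
from artgaps.exposure import calendars_for_cohort
from artgaps.outcomes import outcomes_frame, summarize_cohort

config = AnalysisConfig()
bundle = generate_bundle(SimulationParams(n_beneficiaries=500, seed=1), config)
cohort, attrition = apply_selection(identify_index_events(bundle, config),
                                    bundle, config)
print(attrition.to_string(index=False))
outcomes = outcomes_frame(calendars_for_cohort(bundle, cohort, config).values(),
                          config)
summary = summarize_cohort(outcomes, cohort, config)
print(summary[["Overall", "INSTI", "NNRTI", "PI"]].round(3).head(6))
```

prints

```
                                                     criterion  n_remaining
               New anchor medication initiated in index window          500
Continuous Part A/B/D enrollment 12 months pre- and post-index          500
                    HIV diagnosis in 12-month pre-index period          500
                        No death in 12-month post-index period          484
                 Non-missing age, sex, and county of residence          484
              Single anchor medication initiated on index date          484
               Overall    INSTI   NNRTI      PI
N              484.000  317.000  84.000  83.000
PDC mean         0.896    0.896   0.888   0.905
PDC sd           0.190    0.188   0.213   0.180
PDC >= 0.70 n  435.000  285.000  75.000  75.000
PDC >= 0.70 %   89.876   89.905  89.286  90.361
PDC >= 0.80 n  429.000  279.000  75.000  75.000
```

Of 500 simulated beneficiaries, 16 die during follow-up and 484 form the
cohort; mean PDC is 0.896, 59.7% reach optimal adherence, and 51 (10.5%)
discontinue — numbers that move with the generator's stopping hazard and
refill-delay settings, not constants.

The same pipeline runs from the shell:

```bash
artgaps run --out runs/demo --seed 1 --n 500
artgaps measure --bundle-dir runs/demo --dump-calendars   # per-day C/F/G strings
```

## Table schemas

Bundles are directories of five CSV files (UTF-8, ISO-8601 dates;
`write_bundle(..., fmt="parquet")` gives an equivalent columnar binary
option).  One example row each:

| file | columns (example row) |
|---|---|
| `beneficiaries.csv` | `beneficiary_id,birth_date,sex,race_ethnicity,lis_status,eligibility_reason,census_region,metro,plan_type,county_code,hcc_score,rx_per_month_pre,death_date,enrollment_months,cm_*` — `B000001,1958-04-01,male,White,full,disability,South,urban,other,01001,1.04,5.2,,2014-05;2014-06;...,0,1,...` |
| `prescriptions.csv` | `beneficiary_id,fill_date,drug_id,days_supply,quantity` — `B000001,2015-06-01,INSTI_STR_01,30,30.0` |
| `stays.csv` | `beneficiary_id,admit_date,discharge_date,setting` — `B000001,2015-08-03,2015-08-09,hospital` |
| `diagnoses.csv` | `beneficiary_id,service_date,code,code_system,setting` — `B000001,2015-01-15,B20,ICD10CM,outpatient` |
| `drug_catalog.csv` | `drug_id,anchor_class,str_flag` — `INSTI_STR_01,INSTI,STR` |

`enrollment_months` lists the calendar months with joint Part A/B/D
fee-for-service coverage as semicolon-joined `YYYY-MM` tokens; `cm_*`
columns are 0/1 comorbidity-group flags (unknown flag names are carried
through untouched).  `artgaps config init` writes the default
`AnalysisConfig` as YAML.

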