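# Data dictionary

All tables are CSV with a header row; dates are ISO-8601 (`YYYY-MM-DD`);
list-valued fields are semicolon-separated. Unparseable rows are collected
in a reject log (`table,row,reason`), never silently dropped.

## Input tables

### fills.csv (PDMP-style dispensing records)
| column | type | notes |
|---|---|---|
| patient_id | string | opaque identifier |
| prescriber_id | string | may be empty (removed during cleaning) |
| fill_date | date | |
| drug_base | enum | hydrocodone, oxycodone, codeine, tramadol, morphine, hydromorphone, other |
| combination_ingredient | enum | none, acetaminophen, ibuprofen, other |
| strength_per_unit | float | mg per tablet |
| quantity | float | tablet count; cleaned fills have quantity ≥ 4 and < the percentile cutoff |
| days_supply | int | cleaned fills have 0 ≤ days_supply ≤ 90 |
| long_acting | bool | long-acting formulations never index |

### spans.csv (enrollment spans)
| column | type | notes |
|---|---|---|
| patient_id | string | |
| start_date / end_date | date | half-open `[start, end)`; spans may abut or overlap |
| plan | enum | commercial, medicaid, medicare, dual, unknown |

### claims.csv (ED / inpatient encounters)
| column | type | notes |
|---|---|---|
| patient_id | string | |
| service_date | date | |
| setting | enum | ED, inpatient |
| diagnosis_codes | list | ICD-10 codes, uppercase, `;`-separated |

### deaths.csv (vital records)
| column | type | notes |
|---|---|---|
| patient_id | string | at most one row per patient |
| death_date | date | |
| underlying_cause | string | ICD-10 |
| multiple_causes | list | ICD-10, `;`-separated |
| literal_text | string | death-certificate free text |

### demographics.csv
| column | type | notes |
|---|---|---|
| patient_id | string | |
| age_years | int | as of the configurable reference date; cohort members are ≥ 18 |
| gender | enum | F, M |
| race_ethnicity | enum | White, Black, Hispanic, Asian-Pacific Islander, Other, Unknown |
| urbanization | enum | 6-level NCHS scheme + unknown |

## Pipeline outputs

* `fills_clean.csv`, `removal_log.csv` — cleaned fills and reason-coded removals.
* `index_events.csv`, `exclusions.csv` — qualifying index fills; reason-coded enrollment exclusions.
* `cohort.csv` — one row per patient: drug_group, subgroup_drug, age/MME/days-supply categories, gender, race, insurance, urbanization, index year/date, index MME, prescriber.
* `chronic.csv` — fills in 365 d, total/average uncovered days, both chronic flags, episode length, total days' supply.
* `overdose_events.csv` — event date, fatal flag, source (death_codes, death_literal, ED_claim, inpatient_claim).
* `survival.csv` — survival_days, event, censor_reason (enrollment_loss, non_opioid_death, study_end, none).
* `secondary.csv` — cumulative 6-month MME, any_additional_fill, switched (empty when not applicable).
* `model_*.json` / `model_*.txt` — serialized model reports; `table1–3.csv` — balance and outcome tables.
* `manifest.json` — seed, config hash, stage timings, and every output file with row count and SHA-256.

## Shipped resources

* `resources/mme_factors.csv` — drug_base → MME per mg (CDC factors).
* `resources/overdose_codes.yaml` — overdose code set (underlying causes, T-code prefixes, non-fatal prefixes, literal terms); editable and loadable via `load_code_set(path)`.
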